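"""Sectioned pathology report container.

Reports follow the three-section dermatopathology convention::

    Final diagnosis: <...> Microscopic findings: <...> Critical findings: <...>

Parsing is lossless: the report text is split into segments at section
markers and concatenating the segments reproduces the original string
byte-for-byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["Report", "SECTION_MARKERS"]

SECTION_MARKERS = (
    "Final diagnosis:",
    "Microscopic findings:",
    "Critical findings:",
)

_MARKER_KEYS = {
    "Final diagnosis:": "diagnosis",
    "Microscopic findings:": "microscopic",
    "Critical findings:": "critical",
}

_MARKER_RE = re.compile("|".join(re.escape(m) for m in SECTION_MARKERS))


@dataclass
class Report:
    """A pathology report with section accessors.

    ``segments`` is the lossless decomposition: a list of
    ``(marker_or_None, substring)`` pairs where each substring *includes*
    its leading marker; their concatenation equals :attr:`text`.
    """

    text: str
    segments: list[tuple[str | None, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.segments = self._split(self.text)

    @staticmethod
    def _split(text: str) -> list[tuple[str | None, str]]:
        segments: list[tuple[str | None, str]] = []
        matches = list(_MARKER_RE.finditer(text))
        if not matches or matches[0].start() > 0:
            head_end = matches[0].start() if matches else len(text)
            segments.append((None, text[:head_end]))
        for i, m in enumerate(matches):
            end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
            segments.append((m.group(0), text[m.start():end]))
        return segments

    def _section(self, marker: str) -> str | None:
        for mk, seg in self.segments:
            if mk == marker:
                body = seg[len(marker):]
                # trim up to nothing: body is raw; accessor strips whitespace
                return body.strip()
        return None

    @property
    def diagnosis(self) -> str | None:
        """Content of the final-diagnosis section (marker stripped)."""
        return self._section("Final diagnosis:")

    @property
    def microscopic(self) -> str | None:
        return self._section("Microscopic findings:")

    @property
    def critical(self) -> str | None:
        return self._section("Critical findings:")

    @property
    def sections(self) -> dict[str, str]:
        """Present sections keyed by short name."""
        out = {}
        for mk, _ in self.segments:
            if mk is not None:
                out[_MARKER_KEYS[mk]] = self._section(mk)  # type: ignore[assignment]
        return out

    def has_all_sections(self) -> bool:
        present = {mk for mk, _ in self.segments if mk is not None}
        return present == set(SECTION_MARKERS)

    def reconstruct(self) -> str:
        return "".join(seg for _, seg in self.segments)

    def __str__(self) -> str:
        return self.text
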