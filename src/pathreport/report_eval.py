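"""Semantic report evaluation: keyword overlap, fuzzy matching, cosine
similarity, and random-report baselines.

Keyword extraction runs either in dictionary mode (a curated vocabulary,
matched case-insensitively as whole phrases) or through a pluggable
named-entity extractor.  Whether a keyword "occurs" in a text is decided
by Gestalt (Ratcliff-Obershelp) pattern matching over word-count-aligned
windows with a cutoff of 0.6, so inflected forms still match.  The
headline score is a Jaccard index over the matched keyword sets, and two
random-pairing baselines (cross-diagnosis and same-diagnosis) bracket
the scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from difflib import SequenceMatcher
from typing import Callable, Protocol, Sequence

import numpy as np

from .report import Report

__all__ = [
    "KeywordMatchResult",
    "SimilarityScore",
    "VocabularyExtractor",
    "extract_keywords",
    "gestalt_ratio",
    "fuzzy_find",
    "keyword_jaccard",
    "CountEmbedder",
    "embedding_similarity",
    "baseline_scores",
]


@dataclass
class KeywordMatchResult:
    reference_terms: set[str]
    generated_terms: set[str]
    matched: set[str]
    jaccard: float
    degenerate: bool = False  # both term sets empty


@dataclass
class SimilarityScore:
    cosine: float
    embedder_name: str


# ---------------------------------------------------------------------------
# keyword extraction
# ---------------------------------------------------------------------------

class KeywordExtractor(Protocol):
    """Pluggable extractor interface (dictionary or NER backed)."""

    def __call__(self, text: str) -> set[str]: ...


class VocabularyExtractor:
    """Dictionary-mode extractor over a curated keyword vocabulary.

    Terms are matched case-insensitively as whole phrases on word
    boundaries; overlapping vocabulary entries are all reported (no
    longest-match suppression), and each term counts once.
    """

    def __init__(self, vocabulary: Sequence[str]):
        terms = [t.strip().lower() for t in vocabulary if t.strip()]
        if not terms:
            raise ValueError("dictionary mode requires a non-empty vocabulary")
        self.vocabulary = sorted(set(terms))
        self._patterns = {
            t: re.compile(r"(?<!\w)" + re.escape(t) + r"(?!\w)") for t in self.vocabulary
        }

    @classmethod
    def from_file(cls, path) -> "VocabularyExtractor":
        lines = open(path, encoding="utf-8").read().splitlines()
        return cls(lines)

    def __call__(self, text: str) -> set[str]:
        low = text.lower()
        return {t for t, pat in self._patterns.items() if pat.search(low)}


def extract_keywords(text: str, extractor: KeywordExtractor) -> set[str]:
    """Term set of a text under the configured extractor."""
    if not text:
        return set()
    return set(extractor(text))


# ---------------------------------------------------------------------------
# gestalt matching
# ---------------------------------------------------------------------------

def gestalt_ratio(a: str, b: str) -> float:
    """Ratcliff-Obershelp similarity 2M/(|a|+|b|).

    M counts the characters covered by recursively located longest
    matching blocks; two empty strings are defined as identical (1.0).
    """
    if not a and not b:
        return 1.0
    return SequenceMatcher(None, a, b, autojunk=False).ratio()


def _normalize(s: str) -> str:
    return " ".join(s.lower().split())


def fuzzy_find(term: str, text: str, cutoff: float = 0.6) -> bool:
    """Is `term` fuzzy-present in `text`?

    The term is compared against every window of the text with the same
    word count (both lowercased, whitespace-normalised); it matches if
    any window reaches ``gestalt_ratio >= cutoff``.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    term_n = _normalize(term)
    if not term_n:
        return False
    words = _normalize(text).split()
    k = len(term_n.split())
    if k > len(words):
        return False
    for i in range(len(words) - k + 1):
        window = " ".join(words[i : i + k])
        if gestalt_ratio(term_n, window) >= cutoff:
            return True
    return False


def keyword_jaccard(
    reference: Report | str,
    generated: Report | str,
    extractor: KeywordExtractor,
    cutoff: float = 0.6,
    union_mode: str = "symmetric",
) -> KeywordMatchResult:
    """Jaccard overlap of fuzzy-matched keywords between two reports.

    Terms are extracted from both texts; a term is *matched* when it is
    fuzzy-findable in both.  ``union_mode="symmetric"`` (default) scores
    |matched| / |R ∪ G|; ``"reference_only"`` scores recall against the
    reference set alone.  If both term sets are empty the score is 1.0
    for byte-identical texts, else 0.0, flagged as degenerate.
    """
    ref_text = reference.text if isinstance(reference, Report) else reference
    gen_text = generated.text if isinstance(generated, Report) else generated
    R = extract_keywords(ref_text, extractor)
    G = extract_keywords(gen_text, extractor)
    if union_mode not in ("symmetric", "reference_only"):
        raise ValueError("union_mode must be 'symmetric' or 'reference_only'")
    universe = R | G if union_mode == "symmetric" else R
    if not universe:
        score = 1.0 if ref_text == gen_text else 0.0
        return KeywordMatchResult(R, G, set(), score, degenerate=True)
    matched = {
        t
        for t in universe
        if fuzzy_find(t, ref_text, cutoff) and fuzzy_find(t, gen_text, cutoff)
    }
    return KeywordMatchResult(R, G, matched, len(matched) / len(universe))


# ---------------------------------------------------------------------------
# embedding similarity
# ---------------------------------------------------------------------------

class TextEmbedder(Protocol):
    name: str

    def __call__(self, text: str) -> np.ndarray: ...


class CountEmbedder:
    """Bag-of-words count embedder over a fixed vocabulary.

    A deterministic reference embedder standing behind the pluggable
    interface (domain sentence embedders plug in the same way).
    """

    def __init__(self, vocabulary: Sequence[str]):
        self.vocab = sorted({w.lower() for w in vocabulary})
        self._index = {w: i for i, w in enumerate(self.vocab)}
        self.name = f"count-{len(self.vocab)}"

    @classmethod
    def from_texts(cls, texts: Sequence[str]) -> "CountEmbedder":
        words = set()
        for t in texts:
            words.update(re.findall(r"[a-z0-9']+", t.lower()))
        return cls(sorted(words))

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(len(self.vocab))
        for w in re.findall(r"[a-z0-9']+", text.lower()):
            i = self._index.get(w)
            if i is not None:
                vec[i] += 1
        return vec


def embedding_similarity(
    reference: Report | str,
    generated: Report | str,
    embedder: TextEmbedder,
) -> SimilarityScore:
    """Cosine similarity of the two report embeddings."""
    ref_text = reference.text if isinstance(reference, Report) else reference
    gen_text = generated.text if isinstance(generated, Report) else generated
    u = np.asarray(embedder(ref_text), dtype=np.float64)
    v = np.asarray(embedder(gen_text), dtype=np.float64)
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("embedder returned non-finite vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("embedding is a zero vector; cosine undefined")
    return SimilarityScore(float(u @ v / (nu * nv)), getattr(embedder, "name", "unknown"))


# ---------------------------------------------------------------------------
# random-report baselines
# ---------------------------------------------------------------------------

def baseline_scores(
    corpus: Sequence[tuple[Report | str, str]],
    mode: str,
    metric: Callable[[Report | str, Report | str], float],
    rng_seed: int = 0,
    n_pairs: int = 100,
) -> dict:
    """Score random report pairs as reference baselines.

    ``mode="lower"`` pairs reports across different diagnoses;
    ``mode="upper"`` pairs distinct reports sharing a diagnosis.
    Returns per-pair scores plus mean and standard deviation.
    """
    if mode not in ("lower", "upper"):
        raise ValueError("mode must be 'lower' or 'upper'")
    if len(corpus) < 2:
        raise ValueError("need at least two reports")
    rng = np.random.default_rng(rng_seed)
    labels = [lab for _, lab in corpus]

    pairs: list[tuple[int, int]] = []
    if mode == "upper":
        by_label: dict[str, list[int]] = {}
        for i, lab in enumerate(labels):
            by_label.setdefault(lab, []).append(i)
        eligible = [idxs for idxs in by_label.values() if len(idxs) >= 2]
        if not eligible:
            raise ValueError("upper baseline requires two reports sharing a label")
        for _ in range(n_pairs):
            idxs = eligible[int(rng.integers(len(eligible)))]
            i, j = rng.choice(idxs, size=2, replace=False)
            pairs.append((int(i), int(j)))
    else:
        distinct = sorted(set(labels))
        if len(distinct) < 2:
            raise ValueError("lower baseline requires at least two diagnoses")
        for _ in range(n_pairs):
            while True:
                i, j = rng.integers(len(corpus)), rng.integers(len(corpus))
                if labels[int(i)] != labels[int(j)]:
                    pairs.append((int(i), int(j)))
                    break

    scores = np.array([metric(corpus[i][0], corpus[j][0]) for i, j in pairs])
    return {
        "mode": mode,
        "pairs": pairs,
        "scores": scores,
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
    }
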