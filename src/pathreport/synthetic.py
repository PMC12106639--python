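"""Synthetic slides, labels, thicknesses, and templated reports.

This module generates the toy study conditions every other module is
tested against: multi-slide patients, long-tailed class imbalance,
blob-like lesions with a measurable depth, and templated three-section
reports whose keyword content is known exactly.

Geometry convention
-------------------
Each toy slide has a fixed "epidermis" boundary at row
:data:`EPIDERMIS_ROW`; lesions grow downward from it.  Tumor thickness is
the Breslow-like depth from that boundary to the deepest lesion pixel,
converted to millimetres with :data:`MM_PER_PIXEL` (0.01 mm/px, chosen so
toy thicknesses fall in the clinically usual 0-5 mm range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .report import Report

__all__ = [
    "EPIDERMIS_ROW",
    "MM_PER_PIXEL",
    "ToyClassSpec",
    "ToySlide",
    "ToyPatient",
    "ToyCorpus",
    "ConfigurationError",
    "DEFAULT_REGISTRY",
    "DEFAULT_CORPUS_CLASSES",
    "make_class_set",
    "make_toy_slide",
    "measure_thickness",
    "make_report",
    "make_corpus",
    "write_corpus",
]

EPIDERMIS_ROW = 10
MM_PER_PIXEL = 0.01


class ConfigurationError(ValueError):
    """Unknown class label or missing template."""


@dataclass(frozen=True)
class ToyClassSpec:
    """One diagnostic class: visual style plus report vocabulary."""

    name: str
    diagnosis: str
    has_lesion: bool
    lesion_color: tuple[int, int, int]
    markers: tuple[str, ...]  # lowercase keyword phrases, class-exclusive


def _registry_defaults() -> dict[str, ToyClassSpec]:
    specs = [
        ToyClassSpec(
            "background_only", "Scar", False, (0, 0, 0),
            ("scar", "collagen fiber bundles", "orthohyperkeratosis"),
        ),
        ToyClassSpec(
            "blob", "Tumor", True, (120, 80, 160),
            ("tumor", "dermal nodule"),
        ),
        ToyClassSpec(
            "basal_cell_carcinoma", "Basal cell carcinoma", True, (92, 70, 180),
            ("basal cell carcinoma", "basaloid nests", "peripheral palisading"),
        ),
        ToyClassSpec(
            "seborrheic_keratosis", "Seborrheic keratosis", True, (150, 100, 60),
            ("seborrheic keratosis", "horn cysts", "acanthosis"),
        ),
        ToyClassSpec(
            "squamous_cell_carcinoma", "Squamous cell carcinoma", True, (220, 120, 120),
            ("squamous cell carcinoma", "keratin pearls", "keratinocyte atypia"),
        ),
        ToyClassSpec(
            "melanocytic_nevus", "Melanocytic nevus", True, (80, 50, 30),
            ("melanocytic nevus", "nevus cells", "junctional nests"),
        ),
    ]
    return {s.name: s for s in specs}


DEFAULT_REGISTRY: dict[str, ToyClassSpec] = _registry_defaults()

#: default corpus classes: one lesion-free benign class plus two lesion
#: classes with well separated colors -> linearly separable toy problem
DEFAULT_CORPUS_CLASSES = (
    "background_only",
    "basal_cell_carcinoma",
    "seborrheic_keratosis",
)


def make_class_set(k: int) -> dict[str, ToyClassSpec]:
    """Generate ``k`` synthetic lesion classes with distinct colors/markers.

    Used for experiments needing more classes than the named registry
    (e.g. long-tail scaling); marker terms are unique nonsense tokens so
    keyword ground truth stays exact.
    """
    import colorsys

    specs = {}
    for i in range(k):
        r, g, b = colorsys.hsv_to_rgb(i / max(k, 1), 0.6, 0.7)
        specs[f"lesion_class_{i:02d}"] = ToyClassSpec(
            name=f"lesion_class_{i:02d}",
            diagnosis=f"Synthetic lesion {i}",
            has_lesion=True,
            lesion_color=(int(r * 255), int(g * 255), int(b * 255)),
            markers=(f"alphafeature{i:02d}", f"betafeature{i:02d}"),
        )
    return specs


@dataclass
class ToySlide:
    image: np.ndarray  # H×W×3 uint8
    lesion_mask: np.ndarray  # H×W bool
    class_label: str
    thickness_mm: float
    slide_index: int = 0

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.lesion_mask.shape:
            raise ValueError("lesion_mask must match image extent")
        empty = not self.lesion_mask.any()
        if empty != (self.thickness_mm == 0.0):
            raise ValueError("thickness_mm must be 0 iff lesion_mask is empty")


@dataclass
class ToyPatient:
    patient_id: str
    slides: list[ToySlide]
    report: Report
    label: str


@dataclass
class ToyCorpus:
    patients: list[ToyPatient]
    class_frequencies: dict[str, float]
    vocabulary: list[str]
    classes: tuple[str, ...]
    registry: dict[str, ToyClassSpec] = field(repr=False, default_factory=dict)


def measure_thickness(
    lesion_mask: np.ndarray,
    epidermis_row: int = EPIDERMIS_ROW,
    mm_per_pixel: float = MM_PER_PIXEL,
) -> float:
    """Depth of the deepest lesion pixel below the epidermis boundary, in mm."""
    rows = np.nonzero(np.asarray(lesion_mask, dtype=bool).any(axis=1))[0]
    if rows.size == 0:
        return 0.0
    return float((rows.max() - epidermis_row) * mm_per_pixel)


def make_toy_slide(
    class_label: str,
    size: int = 96,
    rng_seed: int = 0,
    slide_index: int = 0,
    registry: dict[str, ToyClassSpec] | None = None,
) -> ToySlide:
    """Render one toy slide: pink tissue, epidermis band, optional lesion blob,
    and a white (glass) margin on the right quarter.

    Deterministic for fixed arguments.
    """
    registry = registry or DEFAULT_REGISTRY
    if class_label not in registry:
        raise ConfigurationError(f"unknown class label: {class_label!r}")
    if size < 64:
        raise ValueError("size must be >= 64")
    spec = registry[class_label]
    rng = np.random.default_rng(rng_seed)

    h = w = size
    tissue_w = (3 * w) // 4
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = (253.0, 253.0, 253.0)  # glass background
    img[:, w - (w - tissue_w):] += rng.normal(0, 0.8, size=(h, w - tissue_w, 3))

    # dermis: pink tissue with speckled nuclei for edge texture
    tissue = np.array([232.0, 214.0, 224.0]) + rng.normal(0, 6.0, size=(h, tissue_w, 3))
    n_nuclei = (h * tissue_w) // 40
    yy = rng.integers(0, h, n_nuclei)
    xx = rng.integers(0, tissue_w, n_nuclei)
    tissue[yy, xx] = np.array([120.0, 60.0, 120.0]) + rng.normal(0, 10.0, size=(n_nuclei, 3))
    img[:, :tissue_w] = tissue

    # epidermis band
    img[:EPIDERMIS_ROW + 1, :tissue_w] = (
        np.array([205.0, 160.0, 185.0])
        + rng.normal(0, 5.0, size=(EPIDERMIS_ROW + 1, tissue_w, 3))
    )

    mask = np.zeros((h, w), dtype=bool)
    if spec.has_lesion:
        max_depth = h - EPIDERMIS_ROW - 4
        depth = int(rng.integers(max(12, size // 6), max_depth))
        half_width = int(rng.integers(tissue_w // 6, tissue_w // 3))
        cx = int(rng.integers(half_width, tissue_w - half_width))
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        cy = EPIDERMIS_ROW + depth / 2.0
        ellipse = ((rows - cy) / (depth / 2.0)) ** 2 + ((cols - cx) / half_width) ** 2 <= 1.0
        ellipse[: EPIDERMIS_ROW, :] = False
        ellipse[:, tissue_w:] = False
        # guarantee the lesion reaches its nominal depth
        ellipse[EPIDERMIS_ROW + depth, cx] = True
        mask = ellipse
        color = np.array(spec.lesion_color, dtype=np.float64)
        img[mask] = color + rng.normal(0, 12.0, size=(int(mask.sum()), 3))

    img = np.clip(img, 0, 255).astype(np.uint8)
    return ToySlide(
        image=img,
        lesion_mask=mask,
        class_label=class_label,
        thickness_mm=measure_thickness(mask),
        slide_index=slide_index,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_MICRO_TEMPLATES = (
    "A section shows {m_and} within the specimen.",
    "The specimen demonstrates {m_and} on examination.",
    "Examination reveals {m_and} throughout the sample.",
)

_CRITICAL_TEMPLATES = (
    "{diagnosis}. Complete excision.",
    "{diagnosis}. Partial excision.",
)


def default_templates(
    registry: dict[str, ToyClassSpec] | None = None,
) -> dict[str, dict[str, tuple[str, ...]]]:
    registry = registry or DEFAULT_REGISTRY
    return {
        name: {"microscopic": _MICRO_TEMPLATES, "critical": _CRITICAL_TEMPLATES}
        for name in registry
    }


def _join_terms(terms: tuple[str, ...]) -> str:
    if len(terms) == 1:
        return terms[0]
    return ", ".join(terms[:-1]) + " and " + terms[-1]


def make_report(
    slide_truth: list[ToySlide],
    templates: dict[str, dict[str, tuple[str, ...]]] | None = None,
    rng_seed: int = 0,
    registry: dict[str, ToyClassSpec] | None = None,
) -> Report:
    """Template a three-section report from ground-truth slides.

    All class marker keywords appear in the microscopic section; when any
    slide carries a lesion the maximum depth is reported as
    ``The tumor thickness is {x:.1f} mm.``
    """
    if not slide_truth:
        raise ValueError("slide_truth must contain at least one slide")
    registry = registry or DEFAULT_REGISTRY
    labels = {s.class_label for s in slide_truth}
    if len(labels) > 1:
        raise ValueError(f"slides carry conflicting class labels: {sorted(labels)}")
    label = slide_truth[0].class_label
    if label not in registry:
        raise ConfigurationError(f"unknown class label: {label!r}")
    templates = templates if templates is not None else default_templates(registry)
    if label not in templates:
        raise ConfigurationError(f"no template bank entry for class {label!r}")
    spec = registry[label]
    rng = np.random.default_rng(rng_seed)

    bank = templates[label]
    micro_t = bank["microscopic"][int(rng.integers(len(bank["microscopic"])))]
    crit_t = bank["critical"][int(rng.integers(len(bank["critical"])))]

    micro = micro_t.format(m_and=_join_terms(spec.markers))
    thickness = max(s.thickness_mm for s in slide_truth)
    if thickness > 0:
        micro += f" The tumor thickness is {thickness:.1f} mm."
    critical = crit_t.format(diagnosis=spec.diagnosis)

    text = (
        f"Final diagnosis: {spec.diagnosis}. "
        f"Microscopic findings: {micro} "
        f"Critical findings: {critical}"
    )
    return Report(text)


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def _power_law_counts(n: int, k: int, exponent: float) -> np.ndarray:
    """Deterministic class counts following ``(rank+1)^-exponent``.

    Largest-remainder rounding; every class gets at least one patient.
    """
    weights = (np.arange(1, k + 1, dtype=np.float64)) ** (-float(exponent))
    probs = weights / weights.sum()
    raw = probs * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    # enforce a minimum of one patient per class
    while (counts == 0).any():
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    return counts


def make_corpus(
    n_patients: int,
    imbalance_exponent: float = 1.0,
    rng_seed: int = 0,
    classes: tuple[str, ...] | None = None,
    registry: dict[str, ToyClassSpec] | None = None,
    slide_size: int = 96,
) -> ToyCorpus:
    """Generate a long-tailed multi-patient corpus with known ground truth.

    Class counts are allocated deterministically from the power law (so
    the rank-frequency relationship is a property of the generator, not a
    sampling accident); patients carry 1-3 serial slides (z = 0, 1, 2).
    """
    registry = registry or DEFAULT_REGISTRY
    classes = tuple(classes) if classes is not None else DEFAULT_CORPUS_CLASSES
    for c in classes:
        if c not in registry:
            raise ConfigurationError(f"unknown class label: {c!r}")
    k = len(classes)
    if n_patients < k:
        raise ValueError(f"n_patients ({n_patients}) must be >= number of classes ({k})")

    rng = np.random.default_rng(rng_seed)
    counts = _power_law_counts(n_patients, k, imbalance_exponent)
    labels = [c for c, n in zip(classes, counts) for _ in range(n)]
    rng.shuffle(labels)

    patients: list[ToyPatient] = []
    for i, label in enumerate(labels):
        n_slides = int(rng.integers(1, 4))
        slides = [
            make_toy_slide(
                label,
                size=slide_size,
                rng_seed=int(rng.integers(0, 2**31)),
                slide_index=z,
                registry=registry,
            )
            for z in range(n_slides)
        ]
        report = make_report(
            slides, rng_seed=int(rng.integers(0, 2**31)), registry=registry
        )
        patients.append(ToyPatient(f"patient_{i:04d}", slides, report, label))

    freqs = {c: float(n) / n_patients for c, n in zip(classes, counts)}
    vocabulary = sorted({m for c in classes for m in registry[c].markers})
    return ToyCorpus(patients, freqs, vocabulary, classes, registry)


def write_corpus(corpus: ToyCorpus, outdir: str | Path) -> None:
    """Write images (PNG), reports (UTF-8 text), labels+thickness (TSV),
    and the keyword vocabulary (TXT)."""
    import pandas as pd
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "reports").mkdir(parents=True, exist_ok=True)
    rows = []
    for p in corpus.patients:
        for s in p.slides:
            Image.fromarray(s.image).save(
                outdir / "images" / f"{p.patient_id}_z{s.slide_index}.png"
            )
        (outdir / "reports" / f"{p.patient_id}.txt").write_text(
            p.report.text, encoding="utf-8"
        )
        rows.append(
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "n_slides": len(p.slides),
                "thickness_mm": max(s.thickness_mm for s in p.slides),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    (outdir / "vocabulary.txt").write_text(
        "\n".join(corpus.vocabulary) + "\n", encoding="utf-8"
    )
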