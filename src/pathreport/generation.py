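"""Stochastic decoding with guidance, ensemble refinement, and field parsing.

Decoding applies temperature scaling, then a top-k restriction, then
nucleus (top-p) truncation — the smallest probability prefix whose mass
reaches ``top_p`` — renormalises and samples.  Guidance seeds the prompt
with a diagnosis: supplied by a human ("Final diagnosis: <label>.") or
predicted by a small subset-restricted classifier over slide-encoder
features.  Ensemble refinement draws several stochastic reports with
derived seeds and aggregates them; the reference aggregator is an
ordered sentence union with exact-duplicate removal.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Protocol, Sequence

import numpy as np

from .fusion_lm import SlideReportModel, log_softmax
from .nn import Tensor, no_grad
from .preprocessing import PatchSet
from .report import Report
from .slide_encoder import SlideLatents

__all__ = [
    "GenerationConfig",
    "LabelLookup",
    "FieldNotFound",
    "NOT_FOUND",
    "sample_next_token",
    "generate",
    "expert_prompt",
    "classifier_guidance",
    "ensemble_refine",
    "sentence_union_aggregate",
    "extract_field",
]


@dataclass(frozen=True)
class GenerationConfig:
    temperature: float = 0.8
    top_p: float = 0.95
    top_k: int = 50
    max_tokens: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0 (0 means greedy)")
        if not (0 < self.top_p <= 1):
            raise ValueError("top_p must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be a positive integer")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")


@dataclass
class LabelLookup:
    """Injective map from class index to diagnosis string."""

    labels: dict[int, str]

    def __post_init__(self) -> None:
        values = list(self.labels.values())
        if len(set(values)) != len(values):
            raise ValueError("label lookup must be injective")

    def __getitem__(self, idx: int) -> str:
        return self.labels[int(idx)]


def sample_next_token(
    logits: np.ndarray,
    config: GenerationConfig,
    rng: np.random.Generator,
) -> int:
    """Temperature / top-k / top-p truncated sampling of one token id."""
    logits = np.asarray(logits, dtype=np.float64)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    if config.temperature == 0:
        return int(np.argmax(logits))
    z = logits / config.temperature
    z = z - z.max()
    probs = np.exp(z)
    probs /= probs.sum()

    order = np.argsort(-probs, kind="stable")
    keep = order[: min(config.top_k, order.size)]
    kept = probs[keep]
    cum = np.cumsum(kept)
    # smallest prefix with cumulative probability >= top_p
    cut = min(int(np.searchsorted(cum, config.top_p, side="left")) + 1, kept.size)
    final_ids = keep[:cut]
    final_p = kept[:cut] / kept[:cut].sum()
    return int(rng.choice(final_ids, p=final_p))


def _decode_loop(
    model: SlideReportModel,
    latents: Tensor | None,
    prompt_ids: np.ndarray,
    config: GenerationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    ids = list(np.asarray(prompt_ids, dtype=np.int64))
    eos = model.tokenizer.eos_id
    max_len = model.fused.lm.config.max_len
    with no_grad():
        for _ in range(config.max_tokens):
            if len(ids) >= max_len:
                break
            logits = model.fused(np.array(ids, dtype=np.int64), latents)
            nxt = sample_next_token(logits.numpy()[-1], config, rng)
            ids.append(nxt)
            if nxt == eos:
                break
    return np.array(ids, dtype=np.int64)


def generate(
    model: SlideReportModel,
    patches: PatchSet | SlideLatents | None,
    prompt: str,
    config: GenerationConfig,
) -> Report:
    """Generate a report from a patient's patches (or precomputed latents).

    Deterministic for a fixed ``config.seed``; decoding stops at the
    end-of-sequence token or ``max_tokens``.
    """
    latents: Tensor | None
    if patches is None:
        latents = None
    elif isinstance(patches, SlideLatents):
        latents = Tensor(patches.values)
    else:
        if patches.features is None or len(patches) == 0:
            raise ValueError("generate requires a non-empty encoded PatchSet")
        with no_grad():
            latents = model.resampler(patches.features, patches.coords).detach()
    rng = np.random.default_rng(config.seed)
    prompt_ids = model.tokenizer.encode(prompt, add_bos=True)
    out_ids = _decode_loop(model, latents, prompt_ids, config, rng)
    return Report(model.tokenizer.decode(out_ids))


def expert_prompt(diagnosis: str | None = None) -> str:
    """Expert-guidance prompt: bare section marker, or marker + label."""
    if diagnosis is None or diagnosis.strip() == "":
        return "Final diagnosis:"
    return f"Final diagnosis: {diagnosis.strip()}."


class SubsetClassifier:
    """Small classifier over slide-encoder features, restricted to a subset.

    ``hidden=None`` fits a multinomial logistic regression; an integer
    fits a single-hidden-layer MLP with that many units (100 for the
    one-vs-rest tasks).
    """

    def __init__(self, class_subset: Sequence[str], hidden: int | None = None, seed: int = 0):
        if len(set(class_subset)) < 2:
            raise ValueError("class subset must contain at least 2 distinct labels")
        self.class_subset = list(class_subset)
        if hidden is None:
            from sklearn.linear_model import LogisticRegression

            self.clf = LogisticRegression(max_iter=2000, random_state=seed)
        else:
            from sklearn.neural_network import MLPClassifier

            self.clf = MLPClassifier(
                hidden_layer_sizes=(hidden,), max_iter=2000, random_state=seed
            )

    def fit(self, features: np.ndarray, labels: Sequence[str]) -> "SubsetClassifier":
        labels = list(labels)
        mask = np.array([lab in self.class_subset for lab in labels])
        for c in self.class_subset:
            if not any(lab == c for lab in labels):
                raise ValueError(f"subset class {c!r} has no training examples")
        self.clf.fit(np.asarray(features)[mask], [l for l in labels if l in self.class_subset])
        return self

    def predict(self, feature: np.ndarray) -> str:
        pred = self.clf.predict(np.atleast_2d(feature))[0]
        assert pred in self.class_subset
        return str(pred)


def pool_latents(latents: SlideLatents | np.ndarray) -> np.ndarray:
    """Mean over latent vectors — the feature used for guidance classifiers."""
    vals = latents.values if isinstance(latents, SlideLatents) else np.asarray(latents)
    return vals.mean(axis=0)


def classifier_guidance(
    latents: SlideLatents,
    class_subset: Sequence[str],
    training_features: np.ndarray,
    training_labels: Sequence[str],
    lookup: LabelLookup | dict[str, str] | None = None,
    hidden: int | None = None,
    seed: int = 0,
) -> str:
    """Predict a diagnosis within an allowed subset and build the prompt.

    A small classifier is fitted on pooled slide-encoder features of the
    training samples restricted to the subset; the prediction is mapped
    through the label lookup into an expert prompt.
    """
    clf = SubsetClassifier(class_subset, hidden=hidden, seed=seed).fit(
        training_features, training_labels
    )
    predicted = clf.predict(pool_latents(latents))
    if isinstance(lookup, LabelLookup):
        predicted = lookup[list(class_subset).index(predicted)]
    elif lookup is not None:
        predicted = lookup[predicted]
    return expert_prompt(predicted)


# ---------------------------------------------------------------------------
# ensemble refinement
# ---------------------------------------------------------------------------

class Aggregator(Protocol):
    def __call__(self, reports: list[Report]) -> Report: ...


_SENTENCE_RE = re.compile(r"[^.]*\.|[^.]+$")


def _split_sentences(text: str) -> list[str]:
    return [s.strip() for s in _SENTENCE_RE.findall(text) if s.strip()]


def sentence_union_aggregate(reports: list[Report]) -> Report:
    """Reference aggregator: ordered sentence union per section.

    Sentences are collected section-by-section across samples in order
    of first appearance; exact duplicates are dropped; the section
    structure of the output mirrors the inputs.
    """
    if not reports:
        raise ValueError("nothing to aggregate")
    markers = ("Final diagnosis:", "Microscopic findings:", "Critical findings:")
    keys = ("diagnosis", "microscopic", "critical")
    parts: list[str] = []
    for marker, key in zip(markers, keys):
        seen: list[str] = []
        for rep in reports:
            body = rep.sections.get(key)
            if body is None:
                continue
            for sent in _split_sentences(body):
                if sent not in seen:
                    seen.append(sent)
        if seen:
            parts.append(marker + " " + " ".join(seen))
    if not parts:  # unsectioned text: union over whole texts
        seen = []
        for rep in reports:
            for sent in _split_sentences(rep.text):
                if sent not in seen:
                    seen.append(sent)
        return Report(" ".join(seen))
    return Report(" ".join(parts))


def ensemble_refine(
    model: SlideReportModel,
    patches: PatchSet | SlideLatents | None,
    prompt: str,
    k: int = 10,
    config: GenerationConfig = GenerationConfig(),
    aggregator: Aggregator | None = None,
) -> tuple[Report, list[Report]]:
    """Sample ``k`` stochastic reports and aggregate them into one.

    Per-sample seeds are derived deterministically from the base seed
    (``SeedSequence(config.seed).spawn``).  If the aggregator raises,
    the sample with the highest self-likelihood under the model is
    returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    aggregator = aggregator or sentence_union_aggregate
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(k)
    ]
    samples = [
        generate(model, patches, prompt, replace(config, seed=s)) for s in child_seeds
    ]
    try:
        combined = aggregator(samples)
    except Exception as err:  # pluggable aggregators may fail (e.g. remote)
        warnings.warn(f"aggregator failed ({err}); returning best single sample")
        combined = _best_by_self_likelihood(model, patches, samples)
    return combined, samples


def _best_by_self_likelihood(
    model: SlideReportModel,
    patches: PatchSet | SlideLatents | None,
    samples: list[Report],
) -> Report:
    from .fusion_lm import lm_loss

    best, best_loss = samples[0], np.inf
    latents = None
    if isinstance(patches, SlideLatents):
        latents = Tensor(patches.values)
    elif isinstance(patches, PatchSet):
        with no_grad():
            latents = model.resampler(patches.features, patches.coords).detach()
    for rep in samples:
        ids = model.tokenizer.encode(rep.text, add_bos=True, add_eos=True)
        if ids.size < 2 or ids.size > model.fused.lm.config.max_len:
            continue
        with no_grad():
            val = float(lm_loss(model.fused, ids, latents).numpy())
        if val < best_loss:
            best, best_loss = rep, val
    return best


# ---------------------------------------------------------------------------
# structured field extraction
# ---------------------------------------------------------------------------

class FieldNotFound:
    """Sentinel for an absent report field (never a silent default)."""

    def __repr__(self) -> str:
        return "NOT_FOUND"

    def __bool__(self) -> bool:
        return False


NOT_FOUND = FieldNotFound()

_THICKNESS_RE = re.compile(
    r"(?:tumou?r\s+thickness|thickness)\D{0,40}?(\d+(?:[.,]\d+)?)\s*mm",
    re.IGNORECASE,
)

_MARGIN_LEXICON_POSITIVE = ("involved", "present at the margin", "extends to the margin")
_MARGIN_LEXICON_NEGATIVE = ("free", "clear", "not involved", "no tumor at the margin")


def extract_field(text: str, field: str):
    """Parse diagnosis, tumor thickness (mm), or margin status from text.

    Returns :data:`NOT_FOUND` when the field is absent.
    """
    if field == "diagnosis":
        m = re.search(r"Final diagnosis:\s*(.*?)(?:Microscopic findings:|Critical findings:|$)", text, re.DOTALL)
        if not m:
            return NOT_FOUND
        value = m.group(1).strip().rstrip(".").strip()
        return value if value else NOT_FOUND
    if field == "thickness_mm":
        m = _THICKNESS_RE.search(text)
        if not m:
            return NOT_FOUND
        return float(m.group(1).replace(",", "."))
    if field == "margin_status":
        low = text.lower()
        if "margin" not in low:
            return NOT_FOUND
        for window in _margin_windows(low):
            for cue in _MARGIN_LEXICON_NEGATIVE:
                if cue in window:
                    return "negative"
            for cue in _MARGIN_LEXICON_POSITIVE:
                if cue in window:
                    return "positive"
        return NOT_FOUND
    raise ValueError(f"unknown field: {field!r}")


def _margin_windows(low_text: str, width: int = 80) -> list[str]:
    return [
        low_text[max(0, m.start() - width) : m.end() + width]
        for m in re.finditer("margin", low_text)
    ]
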