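"""Gradient-attention saliency maps linking generated text to patches.

The slide encoder compresses n patches into m latents; the fused
language model attends to those latents when writing the report.  A
saliency map for a word is built from two ingredients:

* **G** (n × m): per-latent sensitivity of the encoder output to each
  input patch, obtained by backpropagating each latent's mean activation
  to the patch features and reducing the per-feature gradients with an
  L1 norm (the reduction is a documented choice, isolated in
  :func:`_scalarize_gradient`, so L2/max are one-line swaps);
* **A** (T × m): head-averaged cross-attention rows of the *last* XATTN
  layer, one row per generated token, each row on the simplex.

For a target token span, the latent weight vector is the mean of the
corresponding A rows, and the raw patch score is the mean over latents
of G weighted by that vector; scores are then min-max normalised to
[0, 1] (an all-equal raw vector maps to all ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fusion_lm import SlideReportModel, WhitespaceTokenizer
from .nn import Tensor
from .preprocessing import PatchSet
from .report import Report
from .slide_encoder import PerceiverResampler

__all__ = [
    "SaliencyMap",
    "GradAttnIntermediates",
    "compute_G",
    "grad_attention_map",
    "locate_target_tokens",
    "render_heatmap",
]


@dataclass
class SaliencyMap:
    """Per-patch scores in [0, 1] aligned to grid coordinates."""

    scores: np.ndarray
    coords: np.ndarray
    target_span: tuple[int, ...]
    raw_scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.raw_scores = np.asarray(self.raw_scores, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int32)
        if self.scores.shape[0] != self.coords.shape[0]:
            raise ValueError("scores and coords must align")
        if self.scores.min() < -1e-12 or self.scores.max() > 1 + 1e-12:
            raise ValueError("normalized scores must lie in [0, 1]")


@dataclass
class GradAttnIntermediates:
    G: np.ndarray  # num_patches × num_latents
    A: np.ndarray  # num_tokens × num_latents

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.G.shape[1] != self.A.shape[1]:
            raise ValueError("G and A must share the latent dimension")
        if (self.A < -1e-9).any() or not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("A rows must be nonnegative and sum to 1")


def _scalarize_gradient(per_latent_grad: np.ndarray) -> np.ndarray:
    """Reduce an n × d gradient block to one score per patch (L1 norm)."""
    return np.abs(per_latent_grad).sum(axis=1)


def compute_G(
    resampler: PerceiverResampler,
    patches: PatchSet,
) -> np.ndarray:
    """Sensitivity matrix G (num_patches × num_latents).

    Column j is the scalarised gradient of latent j's mean activation
    with respect to each input patch feature vector.
    """
    if patches.features is None:
        raise ValueError("compute_G requires encoded features")
    feats = Tensor(np.asarray(patches.features, dtype=np.float64), requires_grad=True)
    latents = resampler(feats, patches.coords)
    m = latents.shape[0]
    n = len(patches)
    G = np.empty((n, m), dtype=np.float64)
    for j in range(m):
        feats.grad = None
        latents[j].mean().backward()
        G[:, j] = _scalarize_gradient(feats.grad)
    return G


def grad_attention_map(
    G: np.ndarray,
    A: np.ndarray,
    target_tokens,
    coords: np.ndarray | None = None,
) -> SaliencyMap:
    """Weighted-mean saliency: w = mean(A[targets]); raw_i = mean_j G[i,j]·w[j].

    Raw scores are min-max normalised to [0, 1]; an all-equal raw vector
    (including n = 1) normalises to all ones.
    """
    inter = GradAttnIntermediates(G, A)
    if isinstance(target_tokens, (set, frozenset)):
        target_tokens = sorted(target_tokens)
    targets = np.asarray(sorted({int(t) for t in np.atleast_1d(target_tokens)}))
    if targets.size == 0:
        raise ValueError("target token span must be nonempty")
    if targets.min() < 0 or targets.max() >= inter.A.shape[0]:
        raise ValueError("target token index out of range")
    w = inter.A[targets].mean(axis=0)
    raw = (inter.G * w[None, :]).mean(axis=1)
    span = raw.max() - raw.min()
    if span <= 0:
        scores = np.ones_like(raw)
    else:
        scores = (raw - raw.min()) / span
    if coords is None:
        coords = np.column_stack(
            [np.arange(raw.size), np.zeros(raw.size, int), np.zeros(raw.size, int)]
        )
    return SaliencyMap(
        scores=scores,
        coords=coords,
        target_span=tuple(int(t) for t in targets),
        raw_scores=raw,
    )


def locate_target_tokens(
    report: Report,
    phrase: str,
    tokenizer: WhitespaceTokenizer,
) -> set[int]:
    """Token positions whose decoded character span overlaps the phrase.

    All occurrences contribute; a phrase absent from the report raises.
    """
    text = report.text
    low, phrase_low = text.lower(), phrase.lower()
    occurrences = []
    start = 0
    while True:
        i = low.find(phrase_low, start)
        if i < 0:
            break
        occurrences.append((i, i + len(phrase)))
        start = i + 1
    if not occurrences:
        raise ValueError(f"phrase {phrase!r} not found in report")
    _, spans = tokenizer.encode_with_offsets(text)
    hits: set[int] = set()
    for t, (s, e) in enumerate(spans):
        for os_, oe in occurrences:
            if s < oe and os_ < e:  # overlap
                hits.add(t)
    return hits


def saliency_for_phrase(
    model: SlideReportModel,
    patches: PatchSet,
    report: Report,
    phrase: str,
) -> SaliencyMap:
    """End-to-end map: G from the encoder, A from the last XATTN layer of
    a forward pass over the report tokens, targets located by phrase."""
    G = compute_G(model.resampler, patches)
    ids = model.tokenizer.encode(report.text)
    latents = model.resampler(Tensor(patches.features), patches.coords)
    model.fused(ids, latents.detach())
    A = model.fused.last_cross_attention
    if A is None:
        raise RuntimeError("fused model recorded no cross-attention")
    targets = locate_target_tokens(report, phrase, model.tokenizer)
    return grad_attention_map(G, A, targets, coords=patches.coords)


def render_heatmap(
    saliency: SaliencyMap,
    slide_shape: tuple[int, int],
    patch_size: int,
    colormap: str = "inferno",
) -> np.ndarray:
    """RGBA overlay raster: each patch cell filled with its colormapped
    score, alpha proportional to the score."""
    import matplotlib

    h, w = slide_shape
    overlay = np.zeros((h, w, 4), dtype=np.float64)
    cmap = matplotlib.colormaps[colormap]
    for score, (x, y, _z) in zip(saliency.scores, saliency.coords):
        r0, c0 = y * patch_size, x * patch_size
        if r0 + patch_size > h or c0 + patch_size > w:
            raise ValueError(f"patch at grid ({x}, {y}) falls outside the raster")
        rgba = np.array(cmap(float(score)))
        rgba[3] = float(score)
        overlay[r0 : r0 + patch_size, c0 : c0 + patch_size] = rgba
    return overlay


def saliency_table(saliency: SaliencyMap):
    """Per-patch scores as a DataFrame with columns x, y, z, score."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x": saliency.coords[:, 0],
            "y": saliency.coords[:, 1],
            "z": saliency.coords[:, 2],
            "score": saliency.scores,
        }
    )


def write_heatmap(
    saliency: SaliencyMap,
    slide_shape: tuple[int, int],
    patch_size: int,
    png_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    from PIL import Image

    overlay = render_heatmap(saliency, slide_shape, patch_size)
    Image.fromarray((overlay * 255).astype(np.uint8), mode="RGBA").save(png_path)
    if tsv_path is not None:
        saliency_table(saliency).to_csv(tsv_path, sep="\t", index=False)
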