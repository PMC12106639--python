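"""Perceiver-style slide encoder with MIL pretraining.

A fixed set of learned latent vectors cross-attends to an arbitrary
number of patch features, compressing a whole patient (all slides, all
patches) into an ``n_latents × latent_dim`` summary — by default
640 × 1536.  Patch order carries no information unless the factorized
3-D position embedding is enabled, in which case (x, y, z) grid indices
are embedded through learned per-axis tables and added to the patch
features before resampling.

For pretraining, a discardable linear classification head predicts the
patient-level diagnosis from the mean latent (multiple instance
learning); after pretraining only the resampler weights are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    AdamW,
    Linear,
    Module,
    Parameter,
    Tensor,
    TransformerBlock,
    MultiHeadAttention,
    LayerNorm,
    FeedForward,
    no_grad,
)
from .preprocessing import PatchSet

__all__ = [
    "ResamplerConfig",
    "SlideLatents",
    "FactorizedPositionEmbedding",
    "PerceiverResampler",
    "MILHead",
    "mil_classify",
    "resample_slide",
    "MILTrainSettings",
    "pretrain_mil",
]


@dataclass
class ResamplerConfig:
    input_dim: int = 768
    n_latents: int = 640
    latent_dim: int = 1536
    depth: int = 2
    n_heads: int = 8
    ff_mult: int = 4
    use_position_embedding: bool = False
    max_xyz: tuple[int, int, int] = (64, 64, 8)

    def __post_init__(self) -> None:
        if self.n_latents < 1:
            raise ValueError("n_latents must be >= 1")
        if self.latent_dim % self.n_heads != 0:
            raise ValueError("latent_dim must be divisible by n_heads")


@dataclass
class SlideLatents:
    """Fixed-size set summary of a patient's slides (m × k)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("latents must be a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("latents must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


class FactorizedPositionEmbedding(Module):
    """Learned factorized (x, y, z) lookup tables; output = E_x + E_y + E_z."""

    # init scale 0.1 (larger than the 0.02 used for projections) so the
    # positional signal is not negligible against patch features at init
    INIT_STD = 0.1

    def __init__(self, max_xyz: tuple[int, int, int], dim: int, rng: np.random.Generator):
        self.max_xyz = tuple(int(v) for v in max_xyz)
        self.e_x = Parameter(rng.normal(0, self.INIT_STD, size=(self.max_xyz[0], dim)))
        self.e_y = Parameter(rng.normal(0, self.INIT_STD, size=(self.max_xyz[1], dim)))
        self.e_z = Parameter(rng.normal(0, self.INIT_STD, size=(self.max_xyz[2], dim)))

    def __call__(self, coords: np.ndarray) -> Tensor:
        coords = np.asarray(coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be n×3")
        for axis, limit in enumerate(self.max_xyz):
            vals = coords[:, axis]
            if vals.min() < 0 or vals.max() >= limit:
                raise ValueError(
                    f"coordinate axis {axis} out of embedding-table range "
                    f"[0, {limit})"
                )
        return self.e_x[coords[:, 0]] + self.e_y[coords[:, 1]] + self.e_z[coords[:, 2]]


def embed_positions(coords: np.ndarray, table: FactorizedPositionEmbedding) -> Tensor:
    """Factorized positional embedding of (x, y, z) grid coordinates."""
    return table(coords)


class _ResamplerLayer(Module):
    """One cross-attention layer followed by latent self-attention."""

    def __init__(self, cfg: ResamplerConfig, rng: np.random.Generator):
        self.ln_latents = LayerNorm(cfg.latent_dim)
        self.ln_inputs = LayerNorm(cfg.latent_dim)
        self.cross = MultiHeadAttention(cfg.latent_dim, cfg.latent_dim, cfg.n_heads, rng)
        self.ln_ff = LayerNorm(cfg.latent_dim)
        self.ff = FeedForward(cfg.latent_dim, cfg.ff_mult * cfg.latent_dim, rng)
        self.self_block = TransformerBlock(cfg.latent_dim, cfg.n_heads, rng, cfg.ff_mult)

    def __call__(self, latents: Tensor, inputs: Tensor) -> Tensor:
        latents = latents + self.cross(self.ln_latents(latents), self.ln_inputs(inputs))
        latents = latents + self.ff(self.ln_ff(latents))
        return self.self_block(latents)


class PerceiverResampler(Module):
    """Set-to-set encoder: n patch features -> m latent vectors.

    Softmax attention over the patch set makes the map permutation
    invariant when position embeddings are disabled.
    """

    def __init__(self, config: ResamplerConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.latents = Parameter(
            rng.normal(0, 0.02, size=(config.n_latents, config.latent_dim))
        )
        self.pos_embed = (
            FactorizedPositionEmbedding(config.max_xyz, config.input_dim, rng)
            if config.use_position_embedding
            else None
        )
        self.input_proj = Linear(config.input_dim, config.latent_dim, rng)
        self.layers = [_ResamplerLayer(config, rng) for _ in range(config.depth)]
        self.ln_out = LayerNorm(config.latent_dim)

    def __call__(self, features, coords: np.ndarray | None = None) -> Tensor:
        x = features if isinstance(features, Tensor) else Tensor(np.asarray(features, dtype=np.float64))
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("features must be a non-empty n×d matrix")
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"feature dim {x.shape[1]} != configured input_dim "
                f"{self.config.input_dim}"
            )
        if self.pos_embed is not None:
            if coords is None:
                raise ValueError("position embedding enabled but no coords given")
            x = x + self.pos_embed(coords)
        inputs = self.input_proj(x)
        latents: Tensor = self.latents
        for layer in self.layers:
            latents = layer(latents, inputs)
        return self.ln_out(latents)

    @property
    def last_cross_attention(self) -> np.ndarray | None:
        return self.layers[-1].cross.last_attention


class MILHead(Module):
    """Discardable linear classification head over the mean latent."""

    def __init__(self, latent_dim: int, n_classes: int, rng: np.random.Generator):
        self.fc = Linear(latent_dim, n_classes, rng)

    def __call__(self, latents: Tensor) -> Tensor:
        pooled = latents.mean(axis=0)
        return self.fc(pooled)


def mil_classify(latents: SlideLatents | Tensor, head: MILHead) -> np.ndarray:
    """Class probabilities from slide latents: mean-pool, linear map, softmax."""
    t = latents if isinstance(latents, Tensor) else Tensor(latents.values)
    with no_grad():
        probs = head(t).softmax(axis=-1)
    return probs.numpy()


def resample_slide(
    patches: PatchSet,
    resampler: PerceiverResampler,
) -> SlideLatents:
    """Encode a patient's patch features into fixed-size slide latents."""
    if patches.features is None:
        raise ValueError("resample_slide requires encoded features")
    with no_grad():
        out = resampler(patches.features, patches.coords)
    return SlideLatents(out.numpy())


@dataclass
class MILTrainSettings:
    lr: float = 3e-3
    epochs: int = 60
    betas: tuple[float, float] = (0.9, 0.95)
    weight_decay: float = 0.01
    seed: int = 0
    log: list = field(default_factory=list)


def pretrain_mil(
    corpus: list[tuple[PatchSet, int]],
    config: ResamplerConfig,
    settings: MILTrainSettings | None = None,
    n_classes: int | None = None,
    return_head: bool = False,
):
    """Supervised MIL pretraining of the resampler; the head is discarded.

    ``corpus`` holds (encoded PatchSet, integer class label) pairs; the
    label supervises the patient level while patches stay unordered.
    Returns the trained resampler and a per-epoch loss log; the
    classification head is discarded unless ``return_head`` is set
    (useful for held-out evaluation of the pretraining task itself).
    """
    settings = settings or MILTrainSettings()
    labels = sorted({y for _, y in corpus})
    if len(labels) < 2:
        raise ValueError("MIL pretraining requires at least 2 classes present")
    k = n_classes if n_classes is not None else max(labels) + 1

    rng = np.random.default_rng(settings.seed)
    resampler = PerceiverResampler(config, rng)
    head = MILHead(config.latent_dim, k, rng)
    params = resampler.parameters() + head.parameters()
    opt = AdamW(
        params,
        lr=settings.lr,
        betas=settings.betas,
        weight_decay=settings.weight_decay,
    )
    log: list[dict] = []
    order = np.arange(len(corpus))
    for epoch in range(settings.epochs):
        rng.shuffle(order)
        total = 0.0
        for idx in order:
            ps, y = corpus[idx]
            logits = head(resampler(ps.features, ps.coords))
            logp = _log_softmax_vec(logits)
            loss = -logp[int(y)]
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.numpy())
        log.append({"epoch": epoch, "loss": total / len(corpus), "lr": opt.lr})
    if return_head:
        return resampler, log, head
    # classification head deliberately discarded
    return resampler, log


def _log_softmax_vec(logits: Tensor) -> Tensor:
    m = float(logits.numpy().max())
    z = (logits - m).exp().sum().log() + m
    return logits - z
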