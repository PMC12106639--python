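"""Two-phase training orchestration: schedule, accumulation, clipping,
and report paraphrase augmentation.

The optimizer recipe follows the standard large-model setup: AdamW with
betas (0.9, 0.95), weight decay 0.1, epsilon 1e-8; learning rate warmed
up linearly from zero over 10 epochs to 1e-4, then decayed tenfold with
cosine annealing over the remaining epochs; gradient accumulation of 32
micro-batches and global-norm clipping at 1.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .fusion_lm import FusedLM, SlideReportModel, lm_loss
from .nn import AdamW, Tensor, clip_grad_norm
from .report import SECTION_MARKERS, Report

__all__ = [
    "TrainConfig",
    "lr_at_step",
    "RewriteProvider",
    "IdentityProvider",
    "SynonymSwapProvider",
    "augment_reports",
    "train_report_model",
]

#: markers the augmentation prompt forbids changing
_PROTECTED_MARKERS = ("Microscopic findings:", "Critical findings:")


@dataclass
class TrainConfig:
    betas: tuple[float, float] = (0.9, 0.95)
    weight_decay: float = 0.1
    epsilon: float = 1e-8
    peak_lr: float = 1e-4
    warmup_epochs: int = 10
    total_epochs: int = 100
    final_lr_ratio: float = 0.1
    grad_accum: int = 32
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        # total_epochs == 0 is permitted as an explicit no-op run
        if self.total_epochs > 0 and not (0 < self.warmup_epochs < self.total_epochs):
            raise ValueError("require 0 < warmup_epochs < total_epochs")
        for name in ("peak_lr", "final_lr_ratio", "grad_accum", "clip_norm", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lr_at_step(step: int, steps_per_epoch: int, config: TrainConfig) -> float:
    """Learning rate at an optimizer step.

    Linear 0 → peak over the warmup epochs, then cosine peak →
    peak·final_lr_ratio over the remaining epochs; clamped to the final
    value beyond the schedule.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    warmup_steps = config.warmup_epochs * steps_per_epoch
    total_steps = config.total_epochs * steps_per_epoch
    final_lr = config.peak_lr * config.final_lr_ratio
    if step >= total_steps:
        return final_lr
    if step <= warmup_steps:
        return config.peak_lr * step / warmup_steps
    progress = (step - warmup_steps) / (total_steps - warmup_steps)
    return final_lr + 0.5 * (config.peak_lr - final_lr) * (1.0 + np.cos(np.pi * progress))


# ---------------------------------------------------------------------------
# report paraphrase augmentation
# ---------------------------------------------------------------------------

class RewriteProvider(Protocol):
    """Pluggable text-rewriting interface (an external paraphrasing LLM in
    deployment; deterministic reference providers here)."""

    def rewrite(self, text: str, rng: np.random.Generator) -> str: ...


class IdentityProvider:
    def rewrite(self, text: str, rng: np.random.Generator) -> str:
        return text


class SynonymSwapProvider:
    """Deterministic toy paraphraser: swaps filler words via a fixed map,
    never touching section markers or domain keywords."""

    DEFAULT_MAP = {
        "shows": "demonstrates",
        "demonstrates": "shows",
        "reveals": "shows",
        "specimen": "sample",
        "sample.": "specimen.",
        "within": "inside",
        "throughout": "across",
    }

    def __init__(self, mapping: dict[str, str] | None = None):
        self.mapping = dict(mapping or self.DEFAULT_MAP)

    def rewrite(self, text: str, rng: np.random.Generator) -> str:
        words = text.split(" ")
        out = []
        for w in words:
            if w in self.mapping and rng.random() < 0.8:
                out.append(self.mapping[w])
            else:
                out.append(w)
        return " ".join(out)


def _valid_variant(text: str) -> bool:
    return all(m in text for m in _PROTECTED_MARKERS)


def augment_reports(
    report: Report,
    provider: RewriteProvider | None,
    n: int = 9,
    rng_seed: int = 0,
    max_retries: int = 20,
) -> list[Report]:
    """Sample ``n`` paraphrased variants of a report.

    Variants must retain the protected section markers verbatim; invalid
    rewrites are rejected and resampled (bounded retries, then the
    original text is used for that slot).  A missing provider falls back
    to the identity rewriter with a warning.
    """
    if not report.has_all_sections():
        raise ValueError("report must contain all three sections")
    if provider is None:
        warnings.warn("no rewrite provider available; falling back to identity")
        provider = IdentityProvider()
    rng = np.random.default_rng(rng_seed)
    variants: list[Report] = []
    for _ in range(n):
        text = report.text
        for _attempt in range(max_retries):
            candidate = provider.rewrite(report.text, rng)
            if _valid_variant(candidate):
                text = candidate
                break
        variants.append(Report(text))
    return variants


# ---------------------------------------------------------------------------
# report fine-tuning loop
# ---------------------------------------------------------------------------

@dataclass
class TrainLogRow:
    epoch: int
    loss: float
    lr: float
    grad_norm: float


def train_report_model(
    model: FusedLM | SlideReportModel,
    pairs: list[tuple[Tensor | np.ndarray, np.ndarray]],
    config: TrainConfig,
    loss_fn: Callable[..., Tensor] | None = None,
    stop_condition: Callable[[int], bool] | None = None,
) -> list[TrainLogRow]:
    """Fine-tune the fused model on (slide latents, token ids) pairs.

    One micro-batch is one patient; gradients accumulate over
    ``config.grad_accum`` micro-batches (scaled to their mean), the
    global gradient norm is clipped at ``config.clip_norm``, and one
    optimizer update follows.  The freeze policy is assumed applied:
    only parameters with ``requires_grad`` are updated.

    Returns the per-epoch log (mean loss, lr, last post-accumulation
    clipped gradient norm).  ``total_epochs = 0`` is a no-op.  An optional
    ``stop_condition(updates_done)`` is polled after each epoch and ends
    training early when it returns True (e.g. a memorization run stopping
    at perfect token accuracy).
    """
    fused = model.fused if isinstance(model, SlideReportModel) else model
    loss_fn = loss_fn or lm_loss
    trainable = [p for p in fused.parameters() if p.requires_grad]
    if not trainable:
        raise ValueError("no trainable parameters; apply a freeze policy first")
    opt = AdamW(
        trainable,
        lr=0.0,
        betas=config.betas,
        eps=config.epsilon,
        weight_decay=config.weight_decay,
    )
    steps_per_epoch = max(1, int(np.ceil(len(pairs) / config.grad_accum)))
    rng = np.random.default_rng(config.seed)
    log: list[TrainLogRow] = []
    step = 0
    for epoch in range(config.total_epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        last_norm = 0.0
        micro = 0
        opt.zero_grad()
        for j, idx in enumerate(order):
            latents, ids = pairs[idx]
            lat = latents if isinstance(latents, Tensor) or latents is None else Tensor(np.asarray(latents))
            loss = loss_fn(fused, ids, lat)
            val = float(loss.numpy())
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss ({val}) at epoch {epoch}, micro-batch {j}; "
                    "aborting training"
                )
            epoch_loss += val
            (loss * (1.0 / config.grad_accum)).backward()
            micro += 1
            if micro == config.grad_accum or j == len(order) - 1:
                # flush a partial accumulation window at epoch end
                if micro != config.grad_accum:
                    for p in trainable:
                        if p.grad is not None:
                            p.grad *= config.grad_accum / micro
                step += 1
                opt.lr = lr_at_step(step, steps_per_epoch, config)
                last_norm = clip_grad_norm(trainable, config.clip_norm)
                opt.step()
                opt.zero_grad()
                micro = 0
        log.append(
            TrainLogRow(
                epoch=epoch,
                loss=epoch_loss / max(len(pairs), 1),
                lr=opt.lr,
                grad_norm=min(last_norm, config.clip_norm),
            )
        )
        if stop_condition is not None and stop_condition(step):
            break
    return log


def write_train_log(log: list[TrainLogRow], path) -> None:
    """Persist a training log as TSV (epoch, loss, lr, grad_norm)."""
    import pandas as pd

    pd.DataFrame([vars(r) for r in log]).to_csv(path, sep="\t", index=False)
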