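"""Causal language model with tanh-gated cross-attention fusion.

The language model is pluggable; the shipped default is a small causal
transformer (2 layers, 64 dims, toy vocabulary) paired with a whitespace
tokenizer.  Slide latents are injected through XATTN blocks — one after
each language layer by default — whose residual branch is scaled by
``tanh(gate)`` with the gate initialised to 0, so an untrained fused
model is *exactly* the bare language model.  During report fine-tuning
everything except the XATTN blocks (and their gates) is frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Embedding,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    Parameter,
    Tensor,
    TransformerBlock,
    no_grad,
)
from .slide_encoder import PerceiverResampler, SlideLatents

__all__ = [
    "WhitespaceTokenizer",
    "TokenSequence",
    "LMConfig",
    "FusionConfig",
    "CausalLM",
    "XATTNBlock",
    "FusedLM",
    "SlideReportModel",
    "lm_loss",
    "apply_freeze_policy",
    "log_softmax",
]


class WhitespaceTokenizer:
    """Toy tokenizer: whitespace-split words, one id per distinct word.

    Round-trip contract: ``decode(encode(text))`` equals the
    whitespace-normalised text.  Unknown words map to ``<unk>``.
    """

    PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"

    def __init__(self, texts: list[str] | None = None, extra_tokens: list[str] = []):
        self._vocab: dict[str, int] = {}
        for tok in (self.PAD, self.BOS, self.EOS, self.UNK):
            self._vocab[tok] = len(self._vocab)
        words = set()
        for t in texts or []:
            words.update(t.split())
        for w in sorted(words) + list(extra_tokens):
            if w not in self._vocab:
                self._vocab[w] = len(self._vocab)
        self._inverse = {i: w for w, i in self._vocab.items()}

    @property
    def vocab_size(self) -> int:
        return len(self._vocab)

    @property
    def pad_id(self) -> int:
        return self._vocab[self.PAD]

    @property
    def bos_id(self) -> int:
        return self._vocab[self.BOS]

    @property
    def eos_id(self) -> int:
        return self._vocab[self.EOS]

    @property
    def unk_id(self) -> int:
        return self._vocab[self.UNK]

    def encode(self, text: str, add_bos: bool = False, add_eos: bool = False) -> np.ndarray:
        ids = [self._vocab.get(w, self.unk_id) for w in text.split()]
        if add_bos:
            ids = [self.bos_id] + ids
        if add_eos:
            ids = ids + [self.eos_id]
        return np.array(ids, dtype=np.int64)

    def encode_with_offsets(self, text: str) -> tuple[np.ndarray, list[tuple[int, int]]]:
        """Token ids plus (start, end) character spans into ``text``."""
        ids, spans = [], []
        pos = 0
        for w in text.split():
            start = text.index(w, pos)
            end = start + len(w)
            ids.append(self._vocab.get(w, self.unk_id))
            spans.append((start, end))
            pos = end
        return np.array(ids, dtype=np.int64), spans

    def decode(self, ids) -> str:
        words = []
        for i in np.asarray(ids).tolist():
            w = self._inverse.get(int(i), self.UNK)
            if w in (self.PAD, self.BOS, self.EOS):
                continue
            words.append(w)
        return " ".join(words)


@dataclass
class TokenSequence:
    """An id sequence with section-marker bookkeeping."""

    ids: np.ndarray
    vocabulary_size: int
    section_marker_positions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.ids.size and (self.ids.min() < 0 or self.ids.max() >= self.vocabulary_size):
            raise ValueError("token ids out of vocabulary range")

    def __len__(self) -> int:
        return int(self.ids.size)


@dataclass
class LMConfig:
    vocab_size: int = 50
    dim: int = 64
    n_layers: int = 2
    n_heads: int = 4
    max_len: int = 256
    ff_mult: int = 4


@dataclass
class FusionConfig:
    xattn_every: int = 1
    gate_init: float = 0.0
    latent_dim: int = 1536

    def __post_init__(self) -> None:
        if self.xattn_every < 1:
            raise ValueError("xattn_every must be >= 1")


class CausalLM(Module):
    """Small GPT-style decoder: token + position embeddings, pre-norm blocks."""

    def __init__(self, config: LMConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.tok_emb = Embedding(config.vocab_size, config.dim, rng)
        self.pos_emb = Embedding(config.max_len, config.dim, rng)
        self.blocks = [
            TransformerBlock(config.dim, config.n_heads, rng, config.ff_mult)
            for _ in range(config.n_layers)
        ]
        self.ln_f = LayerNorm(config.dim)
        self.lm_head = Linear(config.dim, config.vocab_size, rng, bias=False)

    def embed(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size > self.config.max_len:
            raise ValueError(f"sequence length {ids.size} exceeds max_len")
        return self.tok_emb(ids) + self.pos_emb(np.arange(ids.size))

    def head(self, hidden: Tensor) -> Tensor:
        return self.lm_head(self.ln_f(hidden))

    def __call__(self, ids: np.ndarray) -> Tensor:
        h = self.embed(ids)
        for blk in self.blocks:
            h = blk(h, causal=True)
        return self.head(h)


class XATTNBlock(Module):
    """Tanh-gated cross-attention: hidden + tanh(gate)·CA(hidden, latents)."""

    def __init__(
        self,
        dim: int,
        latent_dim: int,
        n_heads: int,
        rng: np.random.Generator,
        gate_init: float = 0.0,
    ):
        self.ln = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, latent_dim, n_heads, rng)
        self.gate = Parameter(np.array(float(gate_init)))

    def __call__(self, hidden: Tensor, latents: Tensor) -> Tensor:
        return hidden + self.gate.tanh() * self.attn(self.ln(hidden), latents)

    @property
    def last_attention(self) -> np.ndarray | None:
        return self.attn.last_attention


class FusedLM(Module):
    """Causal LM with interleaved XATTN blocks (one after each LM layer
    by default).  With ``latents=None`` — or gates at 0 — the forward
    pass reduces to the bare language model."""

    def __init__(
        self,
        lm: CausalLM,
        fusion: FusionConfig,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(1)
        self.lm = lm
        self.fusion = fusion
        n_xattn = len(
            [i for i in range(lm.config.n_layers) if i % fusion.xattn_every == 0]
        )
        self.xattn_blocks = [
            XATTNBlock(lm.config.dim, fusion.latent_dim, lm.config.n_heads, rng, fusion.gate_init)
            for _ in range(n_xattn)
        ]

    def __call__(self, ids: np.ndarray, latents: Tensor | None = None) -> Tensor:
        h = self.lm.embed(ids)
        xi = 0
        for i, blk in enumerate(self.lm.blocks):
            if latents is not None and i % self.fusion.xattn_every == 0:
                h = self.xattn_blocks[xi](h, latents)
                xi += 1
            h = blk(h, causal=True)
        return self.lm.head(h)

    @property
    def last_cross_attention(self) -> np.ndarray | None:
        """Head-averaged attention rows (tokens × latents) of the last
        XATTN layer from the most recent forward pass."""
        return self.xattn_blocks[-1].last_attention


@dataclass
class SlideReportModel:
    """Full pipeline model: slide encoder + fused language model + tokenizer."""

    resampler: PerceiverResampler
    fused: FusedLM
    tokenizer: WhitespaceTokenizer

    def encode_slides(self, features: np.ndarray, coords: np.ndarray | None = None) -> SlideLatents:
        with no_grad():
            return SlideLatents(self.resampler(features, coords).numpy())


def log_softmax(logits: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax composed from primitives."""
    m = logits.numpy().max(axis=axis, keepdims=True)  # detached shift
    shifted = logits - Tensor(m)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def lm_loss(
    model: FusedLM | CausalLM,
    tokens: np.ndarray | TokenSequence,
    latents: Tensor | SlideLatents | None = None,
) -> Tensor:
    """Mean next-token cross-entropy under the causal mask.

    Position t is predicted from tokens 0..t-1 only; a length-1 sequence
    has no prediction targets and raises.
    """
    ids = tokens.ids if isinstance(tokens, TokenSequence) else np.asarray(tokens)
    if ids.size < 2:
        raise ValueError("lm_loss requires a sequence of length >= 2")
    lat = None
    if latents is not None:
        lat = latents if isinstance(latents, Tensor) else Tensor(latents.values)
    if isinstance(model, FusedLM):
        logits = model(ids, lat)
    else:
        logits = model(ids)
    logp = log_softmax(logits[: ids.size - 1])
    targets = ids[1:]
    picked = logp[np.arange(ids.size - 1), targets]
    return -picked.mean()


def apply_freeze_policy(model: SlideReportModel, phase: str, head: Module | None = None) -> SlideReportModel:
    """Set trainability flags for a training phase.

    ``mil_pretrain``  : only the resampler (and the MIL head, if given)
                        trains; the language side is frozen.
    ``report_finetune``: only XATTN blocks and their gates train; the LM
                        and the resampler are frozen.
    """
    if phase == "report_finetune":
        model.resampler.set_trainable(False)
        model.fused.lm.set_trainable(False)
        for blk in model.fused.xattn_blocks:
            blk.set_trainable(True)
    elif phase == "mil_pretrain":
        model.resampler.set_trainable(True)
        if head is not None:
            head.set_trainable(True)
        model.fused.lm.set_trainable(False)
        for blk in model.fused.xattn_blocks:
            blk.set_trainable(False)
    else:
        raise ValueError(f"unknown training phase: {phase!r}")
    return model
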