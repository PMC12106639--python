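"""Neural building blocks: parameters, layers, attention, transformer blocks.

Initialisation is explicit and seed-controlled: every module takes a
``numpy.random.Generator`` at construction.  Weights follow the common
transformer recipe (normal(0, 0.02) for projections and embeddings,
zeros for biases).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MultiHeadAttention",
    "FeedForward",
    "TransformerBlock",
]


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter traversal and flat state dicts."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.data.size
            for p in self.parameters()
            if p.requires_grad or not trainable_only
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(n_embeddings, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        ids = np.asarray(ids)
        if ids.size and (ids.min() < 0 or ids.max() >= self.weight.shape[0]):
            raise IndexError(
                f"embedding index out of range [0, {self.weight.shape[0]})"
            )
        return self.weight[ids]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        norm = (x - mu) * (var + self.eps) ** -0.5
        return norm * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention with separate query and key/value sources.

    Used both for self-attention (``kv = q`` source) and cross-attention
    (queries from text hidden states or latents, keys/values from another
    set).  Stores the head-averaged attention probabilities of the last
    forward pass in :attr:`last_attention` (rows renormalised to 1), which
    the interpretability module reads.
    """

    def __init__(
        self,
        q_dim: int,
        kv_dim: int,
        n_heads: int,
        rng: np.random.Generator,
    ):
        if q_dim % n_heads != 0:
            raise ValueError("q_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = q_dim // n_heads
        self.q_proj = Linear(q_dim, q_dim, rng)
        self.k_proj = Linear(kv_dim, q_dim, rng)
        self.v_proj = Linear(kv_dim, q_dim, rng)
        self.out_proj = Linear(q_dim, q_dim, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(
        self,
        query: Tensor,
        key_value: Tensor,
        causal: bool = False,
    ) -> Tensor:
        tq = query.shape[0]
        tk = key_value.shape[0]
        h, dh = self.n_heads, self.head_dim

        q = self.q_proj(query).reshape(tq, h, dh).swapaxes(0, 1)  # h × tq × dh
        k = self.k_proj(key_value).reshape(tk, h, dh).swapaxes(0, 1)
        v = self.v_proj(key_value).reshape(tk, h, dh).swapaxes(0, 1)

        scores = (q @ k.T) * (1.0 / np.sqrt(dh))  # h × tq × tk
        if causal:
            mask = np.triu(np.ones((tq, tk), dtype=bool), k=1)
            scores = scores.masked_fill(mask[None, :, :], -1e30)
        attn = scores.softmax(axis=-1)

        # head-mean attention, rows renormalised (mean of simplex rows is
        # already on the simplex; renormalise defensively for numerics)
        mean_attn = attn.data.mean(axis=0)
        self.last_attention = mean_attn / mean_attn.sum(axis=-1, keepdims=True)

        out = (attn @ v).swapaxes(0, 1).reshape(tq, h * dh)
        return self.out_proj(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm self-attention block (optionally causal)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 4):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff = FeedForward(dim, ff_mult * dim, rng)

    def __call__(self, x: Tensor, causal: bool = False) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, causal=causal)
        x = x + self.ff(self.ln2(x))
        return x
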