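"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package are deliberately tiny (two-layer, 64-dim
transformers; a small Perceiver-style set encoder), so a compact numpy
autodiff engine is sufficient: a :class:`Tensor` wraps an ``ndarray``,
records the operation that produced it, and :meth:`Tensor.backward`
accumulates gradients by reverse topological traversal.

Only the primitives the models need are implemented.  Broadcasting is
supported; gradients of broadcast operands are summed back to the
operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected array-like, got Tensor")
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def _from_op(
        cls,
        data: np.ndarray,
        parents: Sequence["Tensor"],
        backward: Callable[[np.ndarray], None],
    ) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = cls(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                if node.grad is None:
                    node.grad = g.copy()
                else:
                    node.grad += g
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                if parent._backward is None and not parent._parents:
                    if parent.grad is None:
                        parent.grad = pg.copy()
                    else:
                        parent.grad += pg
                else:
                    key = id(parent)
                    if key in grads:
                        grads[key] += pg
                    else:
                        grads[key] = np.asarray(pg, dtype=np.float64).copy()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data + b.data

        def backward(g):
            return [(a, _unbroadcast(g, a.shape)), (b, _unbroadcast(g, b.shape))]

        return Tensor._from_op(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            return [(a, -g)]

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def backward(g):
            return [
                (a, _unbroadcast(g * b.data, a.shape)),
                (b, _unbroadcast(g * a.data, b.shape)),
            ]

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)
        out_data = a.data ** p

        def backward(g):
            return [(a, g * p * a.data ** (p - 1.0))]

        return Tensor._from_op(out_data, (a,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            if b.data.ndim == 1:
                if a.data.ndim == 1:
                    ga = g * b.data
                    gb = g * a.data
                else:
                    ga = np.outer(g, b.data).reshape(a.shape)
                    gb = a.data.reshape(-1, a.shape[-1]).T @ g.reshape(-1)
            elif a.data.ndim == 1:
                ga = g @ np.swapaxes(b.data, -1, -2)
                gb = np.outer(a.data, g)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
            return [(a, ga), (b, gb)]

        return Tensor._from_op(out_data, (a, b), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            return [(a, g.reshape(old))]

        return Tensor._from_op(a.data.reshape(shape), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            return [(a, np.swapaxes(g, ax1, ax2))]

        return Tensor._from_op(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return [(a, full)]

        return Tensor._from_op(out_data, (a,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return [(a, np.broadcast_to(g, a.shape).copy())]
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for d in sorted(d % a.ndim for d in ax):
                    g = np.expand_dims(g, d)
            return [(a, np.broadcast_to(g, a.shape).copy())]

        return Tensor._from_op(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[d] for d in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            return [(a, g * out_data)]

        return Tensor._from_op(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            return [(a, g / a.data)]

        return Tensor._from_op(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            return [(a, g * (1.0 - out_data ** 2))]

        return Tensor._from_op(out_data, (a,), backward)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        a = self
        c = np.sqrt(2.0 / np.pi)
        x = a.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            return [(a, g * grad)]

        return Tensor._from_op(out_data, (a,), backward)

    def softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return [(a, out_data * (g - dot))]

        return Tensor._from_op(out_data, (a,), backward)

    def masked_fill(self, mask: np.ndarray, value: float):
        """Where `mask` is True, replace entries with `value` (no gradient there)."""
        a = self
        mask = np.asarray(mask, dtype=bool)
        out_data = np.where(mask, value, a.data)

        def backward(g):
            return [(a, np.where(mask, 0.0, g))]

        return Tensor._from_op(out_data, (a,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        out = []
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append((t, g[tuple(sl)]))
        return out

    return Tensor._from_op(out_data, ts, backward)
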