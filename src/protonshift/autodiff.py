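"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the shift-prediction network needs:
dense matmul, broadcast bias addition, elementwise arithmetic, ReLU,
sigmoid, tanh, row gather/scatter-add (embeddings and message pooling),
concatenation, and masked mean-absolute-error reduction.  Gradients are
accumulated on a tape and released after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "matmul", "add", "sub", "mul", "relu", "sigmoid", "tanh",
           "gather", "scatter_add", "concat", "scale", "add_scalar", "mean_abs"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # free tape references so intermediates can be collected
            t._parents = ()
            t._backward = None


def _make(data, parents, backward, requires_grad=None):
    if requires_grad is None:
        requires_grad = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=requires_grad)
    if requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accumulate(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    # reduce broadcast axes back to t's shape (bias vectors etc.)
    extra = g.ndim - t.data.ndim
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    for ax, n in enumerate(t.data.shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)
    return _make(a.data @ b.data, (a, b), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, g)
        _accumulate(b, g)
    return _make(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, g)
        _accumulate(b, -g)
    return _make(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, g * b.data)
        _accumulate(b, g * a.data)
    return _make(a.data * b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        _accumulate(a, g * c)
    return _make(a.data * c, (a,), backward)


def add_scalar(a: Tensor, c: float) -> Tensor:
    def backward(g):
        _accumulate(a, g)
    return _make(a.data + c, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)
    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # clip to avoid overflow in exp; sigmoid saturates far earlier anyway
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def backward(g):
        _accumulate(a, g * y * (1.0 - y))
    return _make(y, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)

    def backward(g):
        _accumulate(a, g * (1.0 - y * y))
    return _make(y, (a,), backward)


def gather(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``a[idx]``; gradient is a scatter-add back into ``a``."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            _accumulate(a, ga)
    return _make(a.data[idx], (a,), backward)


def scatter_add(a: Tensor, idx: np.ndarray, n_rows: int) -> Tensor:
    """Pool rows of ``a`` by destination index: out[i] = sum of a[j] with idx[j]==i."""
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros((n_rows,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out, idx, a.data)

    def backward(g):
        _accumulate(a, g[idx])
    return _make(out, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def mean_abs(a: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Mean absolute value over rows selected by a boolean mask (all rows if None)."""
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mean_abs: empty mask")
        sel = a.data[mask]
    else:
        sel = a.data
    n = sel.size

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            s = np.sign(a.data) / n
            if mask is not None:
                ga[mask] = s[mask]
            else:
                ga = s
            _accumulate(a, g * ga)
    return _make(np.array(np.abs(sel).mean()), (a,), backward)
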