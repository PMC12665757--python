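"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the graph-attention model needs: broadcasted
arithmetic, matmul, pointwise nonlinearities, reductions, reshape/concat/
narrow, row gather and segment sum (the scatter/gather pair behind attention
softmax over edges and graph-level pooling).  Gradients are accumulated on a
dynamically built tape; correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

_GRAD_ENABLED = True

#: dtype of every tape array; float32 keeps large attention intermediates
#: cheap, float64 is available for high-precision gradient checking
DTYPE = np.float32


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (evaluation-mode forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, seed: Optional[np.ndarray] = None):
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if seed is None else np.asarray(seed, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Optional[Callable[[np.ndarray], None]]) -> Tensor:
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# -- arithmetic -----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bw(g):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), bw)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def bw(g):
        a._accumulate(g * p * a.data ** (p - 1))

    return _make(out_data, (a,), bw)


# -- pointwise nonlinearities --------------------------------------------

def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bw(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), bw)


def log(a: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), bw)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - out_data ** 2))

    return _make(out_data, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bw)


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    slope = np.where(a.data > 0, 1.0, alpha)

    def bw(g):
        a._accumulate(g * slope)

    return _make(a.data * slope, (a,), bw)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    mask = (a.data > lo) & (a.data < hi)

    def bw(g):
        a._accumulate(g * mask)

    return _make(np.clip(a.data, lo, hi), (a,), bw)


# -- reductions and shape ops --------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

    return _make(out_data, (a,), bw)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    def bw(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(out_data, tuple(tensors), bw)


def narrow(a: Tensor, axis: int, start: int, size: int) -> Tensor:
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + size)
    sl = tuple(sl)

    def bw(g):
        full = np.zeros_like(a.data)
        full[sl] = g
        a._accumulate(full)

    return _make(a.data[sl], (a,), bw)


def gather_rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 2-D (or 1-D) tensor; gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.int64)

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _make(a.data[idx], (a,), bw)


def segment_sum(a: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``a`` into ``n_segments`` buckets given by ``idx``."""
    idx = np.asarray(idx, dtype=np.int64)
    out_data = np.zeros((n_segments,) + a.data.shape[1:], dtype=DTYPE)
    np.add.at(out_data, idx, a.data)

    def bw(g):
        a._accumulate(g[idx])

    return _make(out_data, (a,), bw)


def segment_softmax(scores: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of scores within each segment; scores may be (E,) or (E, H).

    The per-segment max shift is treated as a constant (softmax is invariant
    to it, so the gradient is unaffected).
    """
    idx = np.asarray(idx, dtype=np.int64)
    seg_max = np.full((n_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, idx, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shifted = scores - Tensor(seg_max[idx])
    e = exp(shifted)
    denom = segment_sum(e, idx, n_segments)
    return div(e, gather_rows(denom, idx))


# -- parameters and optimizer --------------------------------------------

class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def clip_grad_norm(params: Sequence[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = total ** 0.5
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
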