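"""Minimal vectorized reverse-mode automatic differentiation.

A :class:`Tensor` wraps a float64 ndarray and records the operations
that produced it; :meth:`Tensor.backward` accumulates gradients by
reverse topological traversal.  The op set is exactly what the
GCN/GAT scoring network needs: dense and constant-sparse matmul,
broadcasted arithmetic, the activations (ReLU, LeakyReLU, ELU, exp,
log), row gather / segment-sum (adjoints of each other, used for
neighborhood softmax), concatenation, clipping and reductions.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sparse

__all__ = ["Tensor", "matmul", "spmm", "add", "sub", "mul", "div", "neg",
           "relu", "leaky_relu", "elu", "exp", "log", "gather", "segment_sum",
           "concat", "clip", "mean", "total"]


class Tensor:
    """Node in the autodiff graph holding a float64 array."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    def backward(self) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's .grad."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # operator sugar
    def __matmul__(self, other):
        return matmul(self, other)

    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.array(np.broadcast_to(g, t.value.shape), dtype=np.float64)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(value, parents, backward) -> Tensor:
    out = Tensor(value)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


# ---------------------------------------------------------------- binary ops

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    val = a.value @ b.value

    def bw(g):
        _accum(a, g @ b.value.T)
        _accum(b, a.value.T @ g)

    return _make(val, (a, b), bw)


def spmm(A, x) -> Tensor:
    """Constant sparse matrix times tensor: ``A @ x`` with A fixed."""
    x = _as_tensor(x)
    A = _sparse.csr_matrix(A)
    val = A @ x.value
    At = A.T.tocsr()

    def bw(g):
        _accum(x, At @ g)

    return _make(val, (x,), bw)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g, a.value.shape))
        _accum(b, _unbroadcast(g, b.value.shape))

    return _make(a.value + b.value, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g, a.value.shape))
        _accum(b, _unbroadcast(-g, b.value.shape))

    return _make(a.value - b.value, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g * b.value, a.value.shape))
        _accum(b, _unbroadcast(g * a.value, b.value.shape))

    return _make(a.value * b.value, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bw(g):
        _accum(a, _unbroadcast(g / b.value, a.value.shape))
        _accum(b, _unbroadcast(-g * a.value / b.value ** 2, b.value.shape))

    return _make(a.value / b.value, (a, b), bw)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accum(a, -g)

    return _make(-a.value, (a,), bw)


# ----------------------------------------------------------- elementwise ops

def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.value > 0

    def bw(g):
        _accum(a, g * mask)

    return _make(a.value * mask, (a,), bw)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    grad_factor = np.where(a.value > 0, 1.0, slope)

    def bw(g):
        _accum(a, g * grad_factor)

    return _make(np.where(a.value > 0, a.value, slope * a.value), (a,), bw)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    ex = np.exp(np.minimum(a.value, 0.0))
    val = np.where(a.value > 0, a.value, alpha * (ex - 1.0))

    def bw(g):
        _accum(a, g * np.where(a.value > 0, 1.0, alpha * ex))

    return _make(val, (a,), bw)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    val = np.exp(a.value)

    def bw(g):
        _accum(a, g * val)

    return _make(val, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)

    def bw(g):
        _accum(a, g / a.value)

    return _make(np.log(a.value), (a,), bw)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through-zero gradient outside [lo, hi]."""
    a = _as_tensor(a)
    inside = (a.value >= lo) & (a.value <= hi)

    def bw(g):
        _accum(a, g * inside)

    return _make(np.clip(a.value, lo, hi), (a,), bw)


# -------------------------------------------------------- structural ops

def gather(a, idx, scatter=None) -> Tensor:
    """Row gather ``a[idx]``; adjoint is scatter-add.

    ``scatter`` optionally supplies the precomputed CSR matrix S with
    S[idx[e], e] = 1 so the adjoint runs as a sparse matmul.
    """
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=int)

    def bw(g):
        if scatter is not None:
            _accum(a, scatter @ g)
        else:
            buf = np.zeros_like(a.value)
            np.add.at(buf, idx, g)
            _accum(a, buf)

    return _make(a.value[idx], (a,), bw)


def segment_sum(a, seg_ids, num_segments: int, scatter=None) -> Tensor:
    """Sum rows of ``a`` into ``num_segments`` buckets; adjoint is gather.

    ``scatter`` optionally supplies the same CSR matrix as for
    :func:`gather`, used here for the forward pass.
    """
    a = _as_tensor(a)
    seg_ids = np.asarray(seg_ids, dtype=int)
    if scatter is not None:
        val = scatter @ a.value
    else:
        out_shape = (num_segments,) + a.value.shape[1:]
        val = np.zeros(out_shape, dtype=np.float64)
        np.add.at(val, seg_ids, a.value)

    def bw(g):
        _accum(a, g[seg_ids])

    return _make(val, (a,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.value for t in ts], axis=axis), ts, bw)


def mean(a) -> Tensor:
    a = _as_tensor(a)
    n = a.value.size

    def bw(g):
        _accum(a, np.full_like(a.value, float(g) / n))

    return _make(a.value.mean(), (a,), bw)


def total(a) -> Tensor:
    """Sum of all elements."""
    a = _as_tensor(a)

    def bw(g):
        _accum(a, np.full_like(a.value, float(g)))

    return _make(a.value.sum(), (a,), bw)
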