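"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the pocket-aware DTI model needs: broadcasted
arithmetic, (batched) dense matmul, sparse-constant matmul for graph
convolutions, segment reductions for pooling over ragged graph batches,
softmax, layer normalisation and elementwise nonlinearities.  Gradients are
accumulated by topological sort over the recorded tape.
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}, name={self.name!r})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad or other._parents:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        ax = axes or None
        out = Tensor(self.data.transpose(ax), parents=(self,))
        inv = np.argsort(ax) if ax else None
        out._backward = lambda g: self._accumulate(g.transpose(inv) if inv is not None else g.transpose())
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(DTYPE))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, name: str = "") -> Tensor:
    return Tensor(data, requires_grad=True, name=name)


# -- nonlinearities ---------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, parents=(x,))
    out._backward = lambda g: x._accumulate(g * e)
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    mask = (x.data > lo) & (x.data < hi)
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))
    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])
    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))
    out._backward = bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Rows of a 2-D tensor by integer index; gradient scatter-adds."""
    index = np.asarray(index)
    out = Tensor(x.data[index], parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(full, index, g)
        x._accumulate(full)
    out._backward = bw
    return out


# -- graph-batch primitives -------------------------------------------------

def sparse_matmul(a: sp.spmatrix, x: Tensor) -> Tensor:
    """Constant sparse matrix times tensor (graph propagation step)."""
    a = a.tocsr()
    out = Tensor(a @ x.data, parents=(x,))
    at = a.T.tocsr()
    out._backward = lambda g: x._accumulate(np.asarray(at @ g, dtype=DTYPE))
    return out


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of x within each segment id (rows need not be sorted)."""
    segments = np.asarray(segments)
    data = np.zeros((num_segments,) + x.shape[1:], dtype=DTYPE)
    np.add.at(data, segments, x.data)
    out = Tensor(data, parents=(x,))
    out._backward = lambda g: x._accumulate(g[segments])
    return out


def segment_max(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Elementwise max of rows within each segment; grad flows to argmax rows."""
    segments = np.asarray(segments)
    data = np.full((num_segments,) + x.shape[1:], -np.inf, dtype=DTYPE)
    np.maximum.at(data, segments, x.data)
    out = Tensor(data, parents=(x,))
    winner = (x.data == data[segments])
    # ties: split gradient among maximal rows of the segment
    counts = np.zeros_like(data)
    np.add.at(counts, segments, winner.astype(DTYPE))
    share = winner / np.maximum(counts[segments], 1.0)

    def bw(g):
        x._accumulate(g[segments] * share)
    out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate).astype(DTYPE) / (1.0 - rate)
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out
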