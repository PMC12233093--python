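"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the encoders and losses need: broadcasting
arithmetic, matmul, elementwise exp/log/sqrt/relu, axis reductions, row
gather, and segment sum/max (the scatter primitives used for message
passing and graph pooling).  Gradients are accumulated in float64; the
graph is unwound by topological sort from the loss node.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.T)
        return out

    # -- elementwise ------------------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / (2.0 * val))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(x, requires_grad=True)


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``t[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=int)
    out = Tensor(t.data[idx], parents=(t,))

    def bw(g):
        if not t.requires_grad:
            return
        acc = np.zeros_like(t.data)
        np.add.at(acc, idx, g)
        t._accum(acc)

    out._backward = bw
    return out


def segment_sum(t: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    seg_ids = np.asarray(seg_ids, dtype=int)
    val = np.zeros((num_segments,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(val, seg_ids, t.data)
    out = Tensor(val, parents=(t,))
    out._backward = lambda g: t.requires_grad and t._accum(g[seg_ids])
    return out


def segment_max(t: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment elementwise max over rows (graph readout pooling).

    Every segment must own at least one row.  The gradient routes to the
    first row attaining the max in each segment and column.
    """
    seg_ids = np.asarray(seg_ids, dtype=int)
    n, d = t.data.shape
    val = np.full((num_segments, d), -np.inf)
    np.maximum.at(val, seg_ids, t.data)
    if np.any(np.isinf(val)):
        raise ValueError("segment_max: some segment has no rows")
    # winner row per (segment, column): first row achieving the max
    winners = np.full((num_segments, d), -1, dtype=int)
    for row in range(n - 1, -1, -1):  # reverse so the first match wins
        s = seg_ids[row]
        hit = t.data[row] == val[s]
        winners[s, hit] = row
    out = Tensor(val, parents=(t,))

    def bw(g):
        if not t.requires_grad:
            return
        acc = np.zeros_like(t.data)
        cols = np.arange(d)
        for s in range(num_segments):
            acc[winners[s], cols] += g[s]
        t._accum(acc)

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def l2_normalize_rows(t: Tensor, eps: float = 1e-12) -> Tensor:
    """Rows scaled to unit L2 norm (differentiable)."""
    sq = (t * t).sum(axis=1, keepdims=True)
    return t / (sq + eps).sqrt()


def logsumexp_rows(t: Tensor) -> Tensor:
    """Row-wise log-sum-exp with max-shift stabilization; returns (n, 1)."""
    shift = np.max(t.data, axis=1, keepdims=True)  # constant w.r.t. grad
    return (t - Tensor(shift)).exp().sum(axis=1, keepdims=True).log() + Tensor(shift)
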