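"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole model (autoencoder, attentive message propagation, neural
collaborative-filtering head) is small and dense, so a compact tensor
engine with exactly the operations those components need is sufficient:
matmul, broadcast add/mul, gather (``take``), concatenation, element-wise
nonlinearities, and segment softmax/sum for per-center attention over a
flat edge list.  Everything is float64; graphs here have at most a few
thousand nodes so numerical headroom beats speed.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "cat",
    "maximum",
    "Adam",
    "xavier_uniform",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping.

    Operations build a DAG; :meth:`backward` runs reverse-mode
    accumulation in topological order.  Constants (``requires_grad=False``
    leaves) never store gradients.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._from_op(-a.data, (a,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor._from_op(a.data @ b.data, (a, b), backward)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        a = self
        original = a.data.shape

        def backward(g):
            a._accumulate(g.reshape(original))

        return Tensor._from_op(a.data.reshape(*shape), (a,), backward)

    def take(self, indices) -> "Tensor":
        """Row gather: out[i] = self[indices[i]]."""
        a = self
        idx = np.asarray(indices, dtype=np.intp)

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

        return Tensor._from_op(a.data[idx], (a,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) / n

    # -- nonlinearities --------------------------------------------------
    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        a = self
        mask = np.where(a.data > 0, 1.0, slope)

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._from_op(a.data * mask, (a,), backward)

    def relu(self) -> "Tensor":
        return self.leaky_relu(slope=0.0)

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = _sigmoid(a.data)

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (a,), backward)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - out_data**2))

        return Tensor._from_op(out_data, (a,), backward)

    def log_sigmoid(self) -> "Tensor":
        """Numerically stable ln(sigmoid(x)) = min(x,0) - log1p(exp(-|x|))."""
        a = self
        out_data = np.minimum(a.data, 0.0) - np.log1p(np.exp(-np.abs(a.data)))

        def backward(g):
            a._accumulate(g * _sigmoid(-a.data))

        return Tensor._from_op(out_data, (a,), backward)

    # -- segment ops (flat edge lists) ----------------------------------
    def segment_softmax(self, segments: np.ndarray, num_segments: int) -> "Tensor":
        """Softmax of a 1-D tensor within groups given by ``segments``."""
        a = self
        seg = np.asarray(segments, dtype=np.intp)
        high = np.full(num_segments, -np.inf)
        np.maximum.at(high, seg, a.data)
        shifted = np.exp(a.data - high[seg])
        denom = np.zeros(num_segments)
        np.add.at(denom, seg, shifted)
        alpha = shifted / denom[seg]

        def backward(g):
            if a.requires_grad:
                dot = np.zeros(num_segments)
                np.add.at(dot, seg, alpha * g)
                a._accumulate(alpha * (g - dot[seg]))

        return Tensor._from_op(alpha, (a,), backward)

    def segment_sum(self, segments: np.ndarray, num_segments: int) -> "Tensor":
        """Sum rows of a 2-D tensor into ``num_segments`` buckets."""
        a = self
        seg = np.asarray(segments, dtype=np.intp)
        out_data = np.zeros((num_segments,) + a.data.shape[1:])
        np.add.at(out_data, seg, a.data)

        def backward(g):
            a._accumulate(g[seg])

        return Tensor._from_op(out_data, (a,), backward)

    # -- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def cat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis``; gradient splits back to the inputs."""
    parents = tuple(tensors)
    sizes = [t.data.shape[axis] for t in parents]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(parents, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._from_op(np.concatenate([t.data for t in parents], axis=axis), parents, backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise maximum; ties route the gradient to the first input."""
    mask = a.data >= b.data

    def backward(g):
        a._accumulate(g * mask)
        b._accumulate(g * ~mask)

    return Tensor._from_op(np.maximum(a.data, b.data), (a, b), backward)


def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a list of :class:`Tensor` parameters."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
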