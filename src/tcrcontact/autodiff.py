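"""Minimal reverse-mode automatic differentiation over numpy arrays.

All tensors are float64. The op set is exactly what the attention / prototype
head needs: broadcasting elementwise arithmetic, (batched) matmul, axis
reductions, sigmoid/softplus/exp/log, clamping, a masked softmax, and
stop-gradient constants. Gradients for every op are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "masked_softmax", "concat_stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient and the closure that backpropagates it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # ---- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        # constants (no grad requested, no upstream graph) never store grads
        if not (self.requires_grad or self._parents):
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
            if self.grad.shape != self.data.shape:  # scalar-broadcast guard
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- elementwise arithmetic ------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1.0))
        return out

    # ---- linear algebra ---------------------------------------------------

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad or other._parents:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    def swap_last(self):
        """Transpose the last two axes."""
        out = Tensor(np.swapaxes(self.data, -1, -2), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, -1, -2))
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    # ---- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- nonlinearities ---------------------------------------------------

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # numerically stable
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def softplus(self):
        y = np.logaddexp(0.0, self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(
            g * 0.5 * (1.0 + np.tanh(0.5 * self.data)))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clamp(self, lo=None, hi=None):
        y = np.clip(self.data, lo, hi)
        out = Tensor(y, self.requires_grad, (self,))
        inside = np.ones_like(self.data)
        if lo is not None:
            inside = inside * (self.data > lo)
        if hi is not None:
            inside = inside * (self.data < hi)
        out._backward = lambda g: self._accumulate(g * inside)
        return out

    def maximum(self, other: float):
        """Elementwise max with a scalar; subgradient 1 at the kink (the
        right-derivative), so a parameter initialized exactly at the corner
        can still receive gradient."""
        y = np.maximum(self.data, other)
        out = Tensor(y, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * (self.data >= other))
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=True)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to positions where mask > 0.

    Masked positions receive an attention weight of exactly 0.0, so padded
    keys cannot influence the output even at the bit level. `mask` must
    broadcast against `scores` and is treated as a constant.
    """
    mask = np.asarray(mask, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        neg = np.where(mask > 0, scores.data, -np.inf)
        m = np.max(neg, axis=-1, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = np.where(mask > 0, np.exp(neg - m), 0.0)
    tot = e.sum(axis=-1, keepdims=True)
    tot = np.where(tot > 0, tot, 1.0)
    a = e / tot
    out = Tensor(a, scores.requires_grad, (scores,))

    def bw(g):
        ds = a * (g - (g * a).sum(axis=-1, keepdims=True))
        scores._accumulate(ds)

    out._backward = bw
    return out


def concat_stack(tensors, axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (used to batch per-threshold filters)."""
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad or t._parents for t in tensors), tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    out._backward = bw
    return out
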