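"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute backend for the restoration network and its
differentiable losses.  Only the operations the package needs are
implemented: broadcasted elementwise arithmetic, reductions, a handful of
nonlinearities, 2-D convolution / transposed convolution / max-pooling /
batch normalization (in :mod:`endorestore.nn.functional`), reshape,
concatenation and symmetric padding.

A :class:`Tensor` wraps an ``ndarray`` plus an optional gradient.  Each
operation records a closure that scatters the upstream gradient into its
parents; :meth:`Tensor.backward` runs them in reverse topological order.
Gradients are only accumulated into tensors that require them, so constant
inputs (fixed filter banks, targets) cost nothing extra.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = np.zeros_like(t.data)
        t.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or array) tensor."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            Tensor._accum(self, _unbroadcast(g, self.data.shape))
            Tensor._accum(other, _unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            Tensor._accum(self, -g)

        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._as_tensor(other))

    def __rsub__(self, other):
        return Tensor._as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor._as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            Tensor._accum(self, _unbroadcast(g * other.data, self.data.shape))
            Tensor._accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            Tensor._accum(self, _unbroadcast(g / other.data, self.data.shape))
            Tensor._accum(
                other,
                _unbroadcast(-g * self.data / (other.data * other.data), other.data.shape),
            )

        return Tensor._result(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        return Tensor._as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** p

        def bwd(g):
            Tensor._accum(self, g * p * self.data ** (p - 1))

        return Tensor._result(out_data, (self,), bwd)

    # -- nonlinearities ----------------------------------------------------

    def log(self):
        def bwd(g):
            Tensor._accum(self, g / self.data)

        return Tensor._result(np.log(self.data), (self,), bwd)

    def sqrt(self):
        """Elementwise square root; backward is clamped near zero so a
        gradient through ``sqrt(0)`` stays finite (the forward pass is exact)."""
        root = np.sqrt(self.data)

        def bwd(g):
            denom = np.maximum(2.0 * root, 1e-12)
            Tensor._accum(self, g / denom)

        return Tensor._result(root, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            Tensor._accum(self, g * sign)

        return Tensor._result(np.abs(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            Tensor._accum(self, g * mask)

        return Tensor._result(self.data * mask, (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            Tensor._accum(self, g * s * (1.0 - s))

        return Tensor._result(s, (self,), bwd)

    def clip01(self):
        """Clip to [0, 1] with straight-through-on-interior gradients."""
        mask = (self.data > 0.0) & (self.data < 1.0)

        def bwd(g):
            Tensor._accum(self, g * mask)

        return Tensor._result(np.clip(self.data, 0.0, 1.0), (self,), bwd)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accum(self, np.broadcast_to(g, self.data.shape).copy())

        return Tensor._result(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bwd(g):
            Tensor._accum(self, g.reshape(old))

        return Tensor._result(out_data, (self,), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` (channel fusion for U-Net skips)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            Tensor._accum(t, g[tuple(sl)])

    return Tensor._result(data, tuple(tensors), bwd)
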