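"""Minimal vectorized reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operator set the selective network needs: affine maps,
elementwise nonlinearities (sigmoid, tanh, relu, softplus), broadcasting
arithmetic, reductions, slicing, concatenation and batched matmul.  Gradients
are accumulated by a topological-order backward sweep; broadcasting is undone
by summing over broadcast axes.  Correctness is established by central
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "sigmoid", "tanh", "relu", "softplus",
           "exp", "log", "square", "clip_probs"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")
    __array_priority__ = 100  # keep ndarray.__mul__ from hijacking Tensor ops

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(data, np.ndarray) else data
        self.grad = None
        self._backward = None
        self._prev = _prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; `self` is typically a scalar loss."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._prev:
                visit(p)
            topo.append(node)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data, dtype=np.float64)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, k: float):
        out = Tensor(self.data ** k, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * k * self.data ** (k - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bw
        return out

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data, dtype=np.float64)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ----------------------------------------------------------------- functions

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
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


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))
    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))
    out._backward = bw
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))
    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0))
    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    # numerically stable: log(1+e^x) = max(x,0) + log1p(e^-|x|)
    v = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))
    out = Tensor(v, _prev=(x,))
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        if x.requires_grad:
            x._accum(g * s)
    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * e)
    out._backward = bw
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _prev=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g / x.data)
    out._backward = bw
    return out


def square(x: Tensor) -> Tensor:
    return x * x


def clip_probs(x: Tensor, eps: float = 1e-7) -> Tensor:
    """Clamp probabilities away from {0,1}; gradient passes only inside the band."""
    out = Tensor(np.clip(x.data, eps, 1.0 - eps), _prev=(x,))
    inside = (x.data > eps) & (x.data < 1.0 - eps)

    def bw(g):
        if x.requires_grad:
            x._accum(g * inside)
    out._backward = bw
    return out
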