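"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the attention predictor: broadcast-aware
elementwise arithmetic, batched matrix multiplication, reductions, the
activations the model uses (ELU, sigmoid, leaky ReLU), and a numerically
stable masked softmax. Gradients are accumulated by topological-order
backpropagation from a scalar loss. Data is float64 throughout; the graphs
involved are small, so clarity wins over memory tricks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        def backward(g, a=self, e=exponent):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))
        return self._make(self.data**exponent, (self,), backward)

    def matmul(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accum(_unbroadcast(gb, b.data.shape))
        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def transpose_last(self):
        """Swap the last two axes."""
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(np.swapaxes(g, -1, -2))
        return self._make(np.swapaxes(self.data, -1, -2), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if kd else np.expand_dims(g, ax)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o * (1.0 - o))
        return self._make(out_data, (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        def backward(g, a=self, o=out_data, p=pos, al=alpha):
            if a.requires_grad:
                a._accum(g * np.where(p, 1.0, o + al))
        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        pos = self.data > 0
        def backward(g, a=self, p=pos, s=slope):
            if a.requires_grad:
                a._accum(g * np.where(p, 1.0, s))
        return self._make(np.where(pos, self.data, slope * self.data), (self,), backward)

    # -- plumbing --------------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis, differentiably."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        def backward(g, ts=tensors, sp=splits, ax=axis):
            for t, piece in zip(ts, np.split(g, sp, axis=ax)):
                if t.requires_grad:
                    t._accum(piece)
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, mask: np.ndarray | None = None, axis: int = -1) -> Tensor:
    """Numerically stable softmax; ``mask`` zeros out excluded positions.

    Masked positions receive probability 0; rows that are entirely masked
    come out as all zeros (not NaN), which suits padded graph batches.
    """
    data = x.data
    if mask is not None:
        shifted = x + (-1e30) * (1.0 - mask)
        m = np.max(shifted.data, axis=axis, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        e = (shifted - m).exp() * mask
    else:
        m = np.max(data, axis=axis, keepdims=True)
        e = (x - m).exp()
    denom = e.sum(axis=axis, keepdims=True) + 1e-30
    return e / denom
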