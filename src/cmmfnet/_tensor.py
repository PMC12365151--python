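"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the network needs: broadcast arithmetic,
batched matmul, reshape/transpose/concat, reductions (sum/mean/max),
elementwise nonlinearities and a fused softmax.  Gradients accumulate in
``Tensor.grad`` after :meth:`Tensor.backward` on a scalar.

All data is kept in float64; at the model sizes this package targets the
extra precision is worth more than the speed of float32.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import erf


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _reduce_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape behind it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def const(data) -> "Tensor":
        return Tensor(data, requires_grad=False)

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor.const(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_reduce_to(g, self.shape))
            if other.requires_grad:
                other._accum(_reduce_to(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_reduce_to(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_reduce_to(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out = Tensor(self.data ** e, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_reduce_to(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_reduce_to(gb, other.shape))
        out._backward = bwd
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = bwd
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = tuple(np.argsort(axes))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))
        out._backward = bwd
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        out_data = m if keepdims else np.squeeze(m, axis=axis)
        out = Tensor(out_data, _parents=(self,))
        mask = (self.data == m)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly

        def bwd(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)
        out._backward = bwd
        return out

    # -- elementwise ----------------------------------------------------------
    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))
        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))
        out._backward = bwd
        return out

    def gelu(self) -> "Tensor":
        # exact GELU: x * Phi(x), with Phi the standard normal CDF
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor(x * phi, _parents=(self,))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (phi + x * pdf))
        out._backward = bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))
        out._backward = bwd
        return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis),
                 _parents=tuple(ts))
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bwd
    return out


def layer_norm(x: Tensor, eps: float = 1e-5,
               gain: Tensor | None = None, bias: Tensor | None = None) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, optional affine."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    xhat = centered * (var + eps) ** -0.5
    if gain is not None:
        xhat = xhat * gain
    if bias is not None:
        xhat = xhat + bias
    return xhat


def l2_normalize_rows(x: Tensor, eps: float = 0.0) -> Tensor:
    """Divide each row (last axis) by its Euclidean norm."""
    sq = (x * x).sum(axis=-1, keepdims=True)
    if np.any(sq.data <= 0.0):
        raise ValueError("cannot L2-normalize a zero vector")
    return x * (sq + eps) ** -0.5
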