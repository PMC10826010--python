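"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the adversarial backends need: broadcasting
arithmetic, matmul, piecewise-linear and sigmoidal activations, reductions,
concatenation and elementwise powers. Gradients accumulate into ``.grad``
after calling :meth:`Tensor.backward` on a scalar output.

Broadcasting follows numpy; gradients of broadcast operands are summed back
to the operand's shape.
"""

from __future__ import annotations

import numpy as np

ArrayLike = "np.ndarray | float | int | Tensor"


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    """A numpy array plus the local backward rules that produced it."""

    __slots__ = ("data", "grad", "_parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        # parents: tuple of (Tensor, fn(out_grad) -> grad contribution)
        self._parents = parents

    @property
    def shape(self):
        return self.data.shape

    # ---- graph mechanics -------------------------------------------------

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
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._parents:
                contrib = fn(node.grad)
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad = parent.grad + contrib

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            (
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, ((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            (
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self**-1.0

    def __pow__(self, p: float):
        out = self.data**p
        return Tensor(out, ((self, lambda g: g * p * self.data ** (p - 1.0)),))

    def __matmul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data @ other.data,
            (
                (self, lambda g: g @ other.data.T),
                (other, lambda g: self.data.T @ g),
            ),
        )

    def transpose(self):
        return Tensor(self.data.T.copy(), ((self, lambda g: g.T),))

    # ---- activations -----------------------------------------------------

    def relu(self):
        mask = (self.data > 0).astype(np.float64)
        return Tensor(self.data * mask, ((self, lambda g: g * mask),))

    def leaky_relu(self, alpha: float = 0.2):
        slope = np.where(self.data > 0, 1.0, alpha)
        return Tensor(self.data * slope, ((self, lambda g: g * slope),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, ((self, lambda g: g * (1.0 - out**2)),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor(out, ((self, lambda g: g * out * (1.0 - out)),))

    def exp(self):
        out = np.exp(np.clip(self.data, -60, 60))
        return Tensor(out, ((self, lambda g: g * out),))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor(np.abs(self.data), ((self, lambda g: g * sign),))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, ((self, lambda g: g * 0.5 / np.maximum(out, 1e-300)),))

    # ---- reductions & shaping -------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            g = np.asarray(g)
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor(out, ((self, grad_fn),))

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            denom = self.data.size
        else:
            denom = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), ((self, lambda g: g.reshape(old)),))

    def __getitem__(self, key):
        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return out

        return Tensor(self.data[key], ((self, grad_fn),))


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, tuple((t, make_fn(i)) for i, t in enumerate(tensors)))


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e * (e.sum(axis=axis, keepdims=True) ** -1.0)
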