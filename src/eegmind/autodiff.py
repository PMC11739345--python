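"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports the handful of operations the model stack needs: (batched) matmul,
broadcasting add/mul, ReLU, exp/log, sum/mean/max reductions, concatenation,
reshape/transpose, and a numerically stable masked softmax. Gradients flow
through a topologically sorted backward pass; broadcasting is handled by
summing gradients over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "relu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    for _ in range(nd):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing -----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:
                node.grad = g if node.grad is None else node.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operations ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def matmul(self, other):
        other = self._lift(other)
        a, b = self.data, other.data

        def back(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(a @ b, (self, other), back)

    __matmul__ = matmul

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties

        def back(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (gg * mask,)

        return Tensor._make(
            out_data if keepdims else out_data.squeeze(axis), (self,), back
        )

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a, b):
        return Tensor._make(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, key):
        def back(g):
            out = np.zeros(self.shape)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._make(self.data[key], (self,), back)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def relu(x: Tensor) -> Tensor:
    return x.relu()


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), back)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; masked-out entries get exactly zero.

    ``mask`` is a boolean array broadcastable to ``x`` marking allowed
    entries. Rows with no allowed entries come out all-zero.
    """
    z = x.data
    if mask is not None:
        neg = np.where(mask, 0.0, -np.inf)
        z = z + neg
    zmax = np.max(np.where(np.isfinite(z), z, -np.inf), axis=axis, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)
    ez = np.exp(z - zmax)
    denom = ez.sum(axis=axis, keepdims=True)
    denom = np.where(denom == 0, 1.0, denom)
    s = ez / denom

    def back(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((g - dot) * s,)

    return Tensor._make(s, (x,), back)
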