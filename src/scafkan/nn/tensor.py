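"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the risk models need: broadcasted
arithmetic, (batched) matrix products, the usual smooth nonlinearities,
reductions, shape manipulation, a numerically stable softmax, and custom
primitives (the B-spline design matrix registers one).  Gradients are
accumulated by a topological backward sweep, micrograd-style but
vectorized.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: Optional[np.ndarray] = None
        self._backward: Callable[[], None] = lambda: None
        self._prev: tuple["Tensor", ...] = ()

    # -- construction helpers ---------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _acc(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            self._acc(out.grad)
            other._acc(out.grad)

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            self._acc(out.grad * other.data)
            other._acc(out.grad * self.data)

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward():
            self._acc(out.grad * exponent * self.data ** (exponent - 1.0))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            a, b, g = self.data, other.data, out.grad
            if a.ndim == 1 and b.ndim == 1:
                self._acc(g * b)
                other._acc(g * a)
            elif b.ndim == 1:
                self._acc(np.expand_dims(g, -1) * b)
                other._acc(np.tensordot(g, a, axes=(range(g.ndim), range(g.ndim))))
            elif a.ndim == 1:
                self._acc(g @ np.swapaxes(b, -1, -2))
                other._acc(np.expand_dims(a, -1) * g)
            else:
                self._acc(g @ np.swapaxes(b, -1, -2))
                other._acc(np.swapaxes(a, -1, -2) @ g)

        out = self._make(out_data, (self, other), backward)
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            self._acc(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        out_data = np.log(self.data)

        def backward():
            self._acc(out.grad / self.data)

        out = self._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            self._acc(out.grad * s * (1.0 - s))

        out = self._make(s, (self,), backward)
        return out

    def silu(self):
        """x * sigmoid(x) — the smooth base activation used on KAN edges."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward():
            self._acc(out.grad * (s + self.data * s * (1.0 - s)))

        out = self._make(out_data, (self,), backward)
        return out

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward():
            self._acc(out.grad * (self.data > 0))

        out = self._make(out_data, (self,), backward)
        return out

    def tanh(self):
        t = np.tanh(self.data)

        def backward():
            self._acc(out.grad * (1.0 - t * t))

        out = self._make(t, (self,), backward)
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._acc(np.broadcast_to(g, self.data.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward():
            self._acc(out.grad.reshape(self.data.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        out_data = self.data.transpose(axes)

        def backward():
            self._acc(out.grad.transpose(np.argsort(axes)))

        out = self._make(out_data, (self,), backward)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward():
            g = out.grad
            self._acc(p * (g - (g * p).sum(axis=axis, keepdims=True)))

        out = self._make(p, (self,), backward)
        return out

    @staticmethod
    def concat(tensors: Iterable["Tensor"], axis: int = -1) -> "Tensor":
        tensors = list(tensors)
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                t._acc(g)

        out = Tensor(out_data)
        if _grad_enabled and any(t.requires_grad for t in tensors):
            out.requires_grad = True
            out._prev = tuple(tensors)
            out._backward = backward
        return out

    @staticmethod
    def custom(data: np.ndarray, parents: tuple["Tensor", ...],
               backward_fn: Callable[[np.ndarray], list[Optional[np.ndarray]]]) -> "Tensor":
        """Register a custom primitive.

        ``backward_fn(grad_out)`` must return one gradient (or None) per
        parent, already shaped like that parent.
        """
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)

            def backward():
                for p, g in zip(parents, backward_fn(out.grad)):
                    if g is not None:
                        p._acc(g)

            out._backward = backward
        return out

    # -- autodiff ----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._prev:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            node._backward()

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
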