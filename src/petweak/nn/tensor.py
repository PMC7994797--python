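"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the report and scan models:
broadcast arithmetic, matmul, 3D convolution with ceil-mode "same" padding,
the usual pointwise nonlinearities, axis reductions, reshapes, and row
gathers (embeddings). Rectifier units honor a guided-backpropagation mode in
which negative upstream gradients are zeroed during the backward pass.
"""

from __future__ import annotations

import contextlib
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "guided_backprop",
    "is_grad_enabled",
    "is_guided",
]

_GRAD_ENABLED = True
_GUIDED = False


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (forward passes only)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def guided_backprop():
    """Zero negative gradients at rectifier units during backward passes."""
    global _GUIDED
    prev = _GUIDED
    _GUIDED = True
    try:
        yield
    finally:
        _GUIDED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def is_guided() -> bool:
    return _GUIDED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        requires = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = requires
        if requires:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data.item())

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accumulate(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(out):
            g = out.grad
            if self.requires_grad:
                gs = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(gs, self.shape))
            if other.requires_grad:
                go = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(go, other.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- pointwise nonlinearities -------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                g = out.grad
                if _GUIDED:
                    g = g * (g > 0)
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * y * (1.0 - y))

        return self._make(y, (self,), backward)

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * (1.0 - y * y))

        return self._make(y, (self,), backward)

    def exp(self) -> "Tensor":
        y = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * y)

        return self._make(y, (self,), backward)

    def log(self) -> "Tensor":
        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only inside the interval."""
        mask = (self.data > lo) & (self.data < hi)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(a % self.ndim for a in axes)
                for a in sorted(axes):
                    g = np.expand_dims(g, a)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation --------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inverse))

        return self._make(self.data.transpose(axes), (self,), backward)

    def take_rows(self, indices: Sequence[int]) -> "Tensor":
        """Gather rows along axis 0 (embedding lookup)."""
        idx = np.asarray(indices, dtype=np.intp)

        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        return self._make(self.data[idx], (self,), backward)

    def slice_rows(self, start: int, stop: int) -> "Tensor":
        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[start:stop] = out.grad
                self._accumulate(g)

        return self._make(self.data[start:stop], (self,), backward)

    # -- softmax -------------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backward pass -------------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)
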