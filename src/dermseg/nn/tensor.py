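"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result propagates gradients
to every tensor created with ``requires_grad=True``.  The op set is exactly
what the segmentation networks and their losses need — it is not a general
framework.  All heavy kernels (convolution, batch norm, pooling, resampling)
live in :mod:`dermseg.nn.functional` with hand-written backward passes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep UNet++ graphs overflow recursion
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

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other, dtype=self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, dtype=self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, dtype=self.dtype)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other, dtype=self.dtype) / self

    # -- reductions & pointwise maps --------------------------------------
    def sum(self):
        def bw(g):
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(), _parents=(self,), _backward=bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accum(np.broadcast_to(g / n, self.data.shape))

        return Tensor(self.data.mean(), _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def sigmoid(self):
        z = np.clip(self.data, -60.0, 60.0)  # exp-overflow guard; sigmoid saturates
        s = 1.0 / (1.0 + np.exp(-z))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor(s, _parents=(self,), _backward=bw)

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), _parents=(self,), _backward=bw)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={'set' if self.grad is not None else 'none'})"


def as_tensor(x, dtype=np.float32) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))
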