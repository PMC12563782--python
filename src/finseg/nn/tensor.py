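"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations the segmentation and detection networks
need: broadcasted elementwise arithmetic, matmul, reductions, reshaping,
concatenation, fancy-index gather, and the logistic/ReLU/SiLU
nonlinearities.  Convolution, pooling and the loss kernels live in
:mod:`finseg.nn.functional` as primitive nodes with hand-written
backward passes.

Everything is float32 unless a caller explicitly feeds float64; graphs
are built eagerly and freed after :meth:`Tensor.backward`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _backward=None, _prev=()):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
            if data.dtype not in (np.float32, np.float64):
                data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = _backward
        self._prev = _prev

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._prev:  # free the graph as we go
                node._backward = None
                node._prev = ()
                if node is not self and not node.requires_grad:
                    node.grad = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _binary(a: "Tensor", b: "Tensor", out: np.ndarray, da, db) -> "Tensor":
        need = a.requires_grad or b.requires_grad

        def _bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(da(g), a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(db(g), b.data.shape))

        return Tensor(out, need, _bw if need else None, (a, b) if need else ())

    @staticmethod
    def _unary(a: "Tensor", out: np.ndarray, da) -> "Tensor":
        need = a.requires_grad

        def _bw(g):
            a._accumulate(da(g))

        return Tensor(out, need, _bw if need else None, (a,) if need else ())

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        return Tensor._binary(self, o, self.data + o.data, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._unary(self, -self.data, lambda g: -g)

    def __sub__(self, other):
        o = as_tensor(other)
        return Tensor._binary(self, o, self.data - o.data, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        o = as_tensor(other)
        return Tensor._binary(
            self, o, self.data * o.data, lambda g: g * o.data, lambda g: g * self.data
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        return Tensor._binary(
            self,
            o,
            self.data / o.data,
            lambda g: g / o.data,
            lambda g: -g * self.data / (o.data * o.data),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = self.data**p
        return Tensor._unary(self, out, lambda g: g * p * self.data ** (p - 1))

    def __matmul__(self, other):
        o = as_tensor(other)
        return Tensor._binary(
            self,
            o,
            self.data @ o.data,
            lambda g: g @ o.data.swapaxes(-1, -2),
            lambda g: self.data.swapaxes(-1, -2) @ g,
        )

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        out = np.maximum(self.data, 0)
        mask = self.data > 0
        return Tensor._unary(self, out, lambda g: g * mask)

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        out = np.where(mask, self.data, slope * self.data)
        return Tensor._unary(self, out, lambda g: g * np.where(mask, 1.0, slope))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._unary(self, out, lambda g: g * out * (1 - out))

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = self.data * s
        return Tensor._unary(self, out, lambda g: g * (s + out * (1 - s)))

    def exp(self):
        out = np.exp(np.clip(self.data, -60, 60))
        return Tensor._unary(self, out, lambda g: g * out)

    def log(self):
        return Tensor._unary(self, np.log(self.data), lambda g: g / self.data)

    def arctan(self):
        out = np.arctan(self.data)
        return Tensor._unary(self, out, lambda g: g / (1.0 + self.data * self.data))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._unary(self, out, lambda g: g * 0.5 / np.maximum(out, 1e-12))

    def clip(self, lo, hi):
        out = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._unary(self, out, lambda g: g * mask)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def da(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor._unary(self, out, da)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int | tuple[int, ...], keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)

        def da(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = self.data.max(axis=axis, keepdims=True)
            mask = self.data == full
            # split ties evenly so the gradient check stays symmetric
            share = mask / mask.sum(axis=axis, keepdims=True)
            return gg * share

        return Tensor._unary(self, out, da)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self.data.reshape(shape)
        return Tensor._unary(self, out, lambda g: g.reshape(self.data.shape))

    def transpose(self, *axes):
        out = self.data.transpose(axes)
        inv = np.argsort(axes)
        return Tensor._unary(self, out, lambda g: g.transpose(inv))

    def __getitem__(self, idx):
        out = self.data[idx]

        def da(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return Tensor._unary(self, out, da)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    need = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out, need, _bw if need else None, tuple(tensors) if need else ())


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)
    need = any(t.requires_grad for t in tensors)

    def _bw(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor(out, need, _bw if need else None, tuple(tensors) if need else ())
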