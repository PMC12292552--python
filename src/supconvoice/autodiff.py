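"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every reachable ``Tensor`` with ``requires_grad=True``.  The op set is
deliberately small — exactly what a transformer-style encoder, two MLP heads,
a softmax cross-entropy and a contrastive loss need: broadcasting arithmetic,
(batched) matmul, exp/log/sqrt/power, relu/tanh, axis reductions, transpose
and reshape.

Broadcasting follows numpy; backward passes un-broadcast by summing gradients
over the broadcast axes.  Gradients are plain float64/float32 ndarrays of the
same shape as each tensor's data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
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
    """An ndarray node in a dynamically-built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        """A view of the same data cut out of the graph (no gradient flows)."""
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        # gradients are never mutated in place, so aliasing the incoming
        # array on first touch is safe and avoids a large copy per op
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order
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
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ----------------------------------------------------------- construction
    @staticmethod
    def _binary(a, b, out_data, bwd) -> "Tensor":
        a, b = as_tensor(a), as_tensor(b)
        out = Tensor(out_data, requires_grad=a.requires_grad or b.requires_grad)
        if out.requires_grad:
            out._prev = (a, b)
            out._backward = bwd
        return out

    @staticmethod
    def _unary(a, out_data, bwd) -> "Tensor":
        out = Tensor(out_data, requires_grad=a.requires_grad)
        if out.requires_grad:
            out._prev = (a,)
            out._backward = bwd
        return out

    # ------------------------------------------------------------- arithmetic
    # python scalars take a fast path that neither wraps them as float64
    # tensors (which would promote float32 graphs) nor tracks their gradient
    def __add__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            a, c = self, float(other)

            def bwd(g):
                a._accumulate(g)

            return Tensor._unary(a, a.data + c, bwd)
        a, b = self, as_tensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._binary(a, b, a.data + b.data, bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._unary(a, -a.data, bwd)

    def __sub__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            return self + (-float(other))
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            a, c = self, float(other)

            def bwd(g):
                a._accumulate(g * c)

            return Tensor._unary(a, a.data * c, bwd)
        a, b = self, as_tensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._binary(a, b, a.data * b.data, bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor) and np.ndim(other) == 0:
            return self * (1.0 / float(other))
        a, b = self, as_tensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return Tensor._binary(a, b, a.data / b.data, bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bwd(g):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._unary(a, a.data ** e, bwd)

    def __matmul__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._binary(a, b, a.data @ b.data, bwd)

    # -------------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor._unary(a, out_data, bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._unary(a, np.log(a.data), bwd)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._unary(a, a.data * mask, bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accumulate(g * (1.0 - out_data ** 2))

        return Tensor._unary(a, out_data, bwd)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._unary(a, out_data, bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        """Max reduction; gradient flows to the (first) argmax entries."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            expanded = out_data
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
                expanded = np.expand_dims(out_data, axis=axis)
            mask = (a.data == expanded).astype(a.data.dtype)
            mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0)
            a._accumulate(mask * g)

        return Tensor._unary(a, out_data, bwd)

    # -------------------------------------------------------------- structural
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = a.data.shape

        def bwd(g):
            a._accumulate(g.reshape(old_shape))

        return Tensor._unary(a, a.data.reshape(shape), bwd)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            a._accumulate(g.transpose(inv))

        return Tensor._unary(a, a.data.transpose(axes), bwd)

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.data.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._unary(a, a.data[idx], bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        out._prev = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        out._backward = bwd
    return out
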