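"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; ``Tensor.backward()`` walks the tape in reverse topological order and
accumulates gradients.  Only the operations the package's networks need
are implemented; tensors are NCHW (or any broadcastable shape for
elementwise ops) and keep the floating dtype they are given, so float32
networks and float64 metric evaluations coexist.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # Topological order via iterative DFS.
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- elementwise ----------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data + o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, o.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data * o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g * o.data, self.data.shape),
                _unbroadcast(g * self.data, o.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data / o.data,
            (self, o),
            lambda g: (
                _unbroadcast(g / o.data, self.data.shape),
                _unbroadcast(-g * self.data / o.data**2, o.data.shape),
            ),
        )

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._make(s, (self,), lambda g: (g * s * (1 - s),))

    def log(self):
        return Tensor._make(
            np.log(self.data), (self,), lambda g: (g / self.data,)
        )

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    def square(self):
        return self * self

    # -- reductions / shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return Tensor._make(out, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def __getitem__(self, idx):
        def bwd(g):
            out = np.zeros_like(self.data)
            out[idx] = g
            return (out,)

        return Tensor._make(self.data[idx], (self,), bwd)

    def matmul(self, other: "Tensor"):
        o = self._coerce(other)
        return Tensor._make(
            self.data @ o.data,
            (self, o),
            lambda g: (g @ o.data.T, self.data.T @ g),
        )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


# -- convolution kernels ------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, s: int, p: int) -> np.ndarray:
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c, h, w = x.shape
    ho = (h - kh) // s + 1
    wo = (w - kw) // s + 1
    shape = (n, c, kh, kw, ho, wo)
    st = x.strides
    strides = (st[0], st[1], st[2], st[3], st[2] * s, st[3] * s)
    return np.lib.stride_tricks.as_strided(x, shape, strides), (ho, wo)


def _conv_fwd(x: np.ndarray, w: np.ndarray, s: int, p: int) -> np.ndarray:
    cols, _ = _im2col(x, w.shape[2], w.shape[3], s, p)
    # (O,C,kh,kw) x (N,C,kh,kw,Ho,Wo) -> (O,N,Ho,Wo)
    y = np.tensordot(w, cols, axes=([1, 2, 3], [1, 2, 3]))
    return np.ascontiguousarray(np.moveaxis(y, 0, 1))


def _conv_dw(dy: np.ndarray, x: np.ndarray, w_shape, s: int, p: int) -> np.ndarray:
    cols, _ = _im2col(x, w_shape[2], w_shape[3], s, p)
    # dy (N,O,Ho,Wo) x cols (N,C,kh,kw,Ho,Wo) -> (O,C,kh,kw)
    return np.tensordot(dy, cols, axes=([0, 2, 3], [0, 4, 5]))


def _conv_dx(
    dy: np.ndarray, w: np.ndarray, x_shape, s: int, p: int
) -> np.ndarray:
    n, c, h, w_ = x_shape
    kh, kw = w.shape[2], w.shape[3]
    xp = np.zeros((n, c, h + 2 * p, w_ + 2 * p), dtype=dy.dtype)
    ho, wo = dy.shape[2], dy.shape[3]
    # dcols[n,c,u,v,ho,wo] = sum_o dy[n,o,ho,wo] w[o,c,u,v]
    dcols = np.tensordot(dy, w, axes=([1], [0]))  # (N,Ho,Wo,C,kh,kw)
    dcols = np.moveaxis(dcols, (3, 4, 5), (1, 2, 3))  # (N,C,kh,kw,Ho,Wo)
    for u in range(kh):
        for v in range(kw):
            xp[:, :, u : u + s * ho : s, v : v + s * wo : s] += dcols[:, :, u, v]
    if p:
        return xp[:, :, p:-p, p:-p]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, pad: int) -> Tensor:
    y = _conv_fwd(x.data, w.data, stride, pad)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def bwd(g):
        grads = [
            _conv_dx(g, w.data, x.data.shape, stride, pad),
            _conv_dw(g, x.data, w.data.shape, stride, pad),
        ]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Transposed convolution, zero padding; w shaped (C_in, C_out, kh, kw)."""
    n, cin, h, wd = x.data.shape
    kh, kw = w.data.shape[2], w.data.shape[3]
    out_shape = (n, w.data.shape[1], (h - 1) * stride + kh, (wd - 1) * stride + kw)
    y = _conv_dx(x.data, w.data, out_shape, stride, 0)
    if b is not None:
        y = y + b.data[None, :, None, None]

    def bwd(g):
        grads = [
            _conv_fwd(g, w.data, stride, 0),
            _conv_dw(x.data, g, w.data.shape, stride, 0),
        ]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(y, parents, bwd)
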