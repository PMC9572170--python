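"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the autoencoder architectures in
this package: broadcasting arithmetic, matmul, elementwise nonlinearities,
reductions, reshaping/slicing, sequence reversal, 1-D/2-D patch extraction
(im2col) for convolutions, nearest-neighbour upsampling, and a numerically
stable softmax. Gradients are accumulated through a topologically sorted
tape; all arrays are float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** (-1.0)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def matmul(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, alpha: float = 0.01):
        mask = self.data > 0
        out_data = np.where(mask, self.data, alpha * self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, alpha))

        return Tensor._make(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        hit = self.data == expanded
        hit = hit / hit.sum(axis=axis, keepdims=True)   # split ties evenly

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(g * hit)

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inverse))

        return Tensor._make(out_data, (self,), backward)

    def flip(self, axis: int):
        out_data = np.flip(self.data, axis=axis)

        def backward(g):
            if self.requires_grad:
                self._accum(np.flip(g, axis=axis))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- softmax ------------------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    # -- convolution support ---------------------------------------------------
    def unfold1d(self, kernel: int, stride: int = 1, pad: int = 0):
        """(N, C, L) -> (N, C*kernel, L_out) patch matrix."""
        n, c, length = self.data.shape
        xp = np.pad(self.data, ((0, 0), (0, 0), (pad, pad))) if pad else self.data
        lp = xp.shape[2]
        l_out = (lp - kernel) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)
        win = win[:, :, ::stride, :]                    # (N, C, L_out, k)
        out_data = win.transpose(0, 1, 3, 2).reshape(n, c * kernel, l_out)

        def backward(g):
            if not self.requires_grad:
                return
            gk = g.reshape(n, c, kernel, l_out)
            gp = np.zeros((n, c, lp))
            base = np.arange(l_out) * stride
            for j in range(kernel):
                gp[:, :, base + j] += gk[:, :, j, :]
            self._accum(gp[:, :, pad : pad + length] if pad else gp)

        return Tensor._make(out_data, (self,), backward)

    def unfold2d(self, kernel: tuple, stride: int = 1, pad: int = 0):
        """(N, C, H, W) -> (N, C*kh*kw, H_out*W_out) patch matrix."""
        kh, kw = kernel
        n, c, h, w = self.data.shape
        xp = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else self.data
        hp, wp = xp.shape[2], xp.shape[3]
        h_out = (hp - kh) // stride + 1
        w_out = (wp - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride, :, :]       # (N, C, Ho, Wo, kh, kw)
        out_data = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, h_out * w_out)

        def backward(g):
            if not self.requires_grad:
                return
            gk = g.reshape(n, c, kh, kw, h_out, w_out)
            gp = np.zeros((n, c, hp, wp))
            rows = np.arange(h_out) * stride
            cols = np.arange(w_out) * stride
            for i in range(kh):
                for j in range(kw):
                    gp[:, :, rows[:, None] + i, cols[None, :] + j] += gk[:, :, i, j]
            self._accum(gp[:, :, pad : pad + h, pad : pad + w] if pad else gp)

        return Tensor._make(out_data, (self,), backward)

    def upsample_nearest(self, axis: int, factor: int):
        out_data = np.repeat(self.data, factor, axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            shape = list(self.data.shape)
            shape[axis : axis + 1] = [shape[axis], factor]
            self._accum(g.reshape(shape).sum(axis=axis + 1))

        return Tensor._make(out_data, (self,), backward)

    # -- autodiff driver ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent in node._prev:
                visit(parent)
            topo.append(node)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self):
        return Tensor(self.data.copy())


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
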