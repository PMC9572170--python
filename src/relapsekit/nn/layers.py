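"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, stack

__all__ = [
    "Module", "Linear", "Dropout", "Conv1d", "Conv2d", "MaxPool2d",
    "BatchNorm1d", "LayerNorm", "GRU", "MultiheadSelfAttention",
    "positional_encoding",
]


class Module:
    """Base class: parameter discovery, train/eval mode, weight snapshots."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, snapshot):
        for p, saved in zip(self.parameters(), snapshot):
            p.data = saved.copy()

    def n_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))


def _kaiming(rng, fan_in, shape):
    return rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Conv1d(Module):
    """Cross-correlation over (N, C, L) with zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng,
                 stride: int = 1, pad: int | None = None):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.pad = pad if pad is not None else kernel // 2
        self.weight = Tensor(_kaiming(rng, c_in * kernel, (c_out, c_in * kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros((c_out, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        patches = x.unfold1d(self.kernel, self.stride, self.pad)
        return self.weight @ patches + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng,
                 stride: int = 1, pad: int | None = None):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.pad = pad if pad is not None else kernel // 2
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(_kaiming(rng, fan_in, (c_out, fan_in)), requires_grad=True)
        self.bias = Tensor(np.zeros((c_out, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        h_out = (h + 2 * self.pad - self.kernel) // self.stride + 1
        w_out = (w + 2 * self.pad - self.kernel) // self.stride + 1
        patches = x.unfold2d((self.kernel, self.kernel), self.stride, self.pad)
        out = self.weight @ patches + self.bias
        return out.reshape(n, -1, h_out, w_out)


class MaxPool2d(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        f = self.factor
        x = x.reshape(n, c, h // f, f, w // f, f)
        return x.max(axis=5).max(axis=3)


class BatchNorm1d(Module):
    """Per-channel normalization of (N, C, L) batches with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1))
        self.running_var = np.ones((1, channels, 1))
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            return self.gamma * (xc * (var + self.eps) ** -0.5) + self.beta
        xn = (x - Tensor(self.running_mean)) * Tensor(
            (self.running_var + self.eps) ** -0.5)
        return self.gamma * xn + self.beta


class LayerNorm(Module):
    def __init__(self, size: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(size), requires_grad=True)
        self.beta = Tensor(np.zeros(size), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc * (var + self.eps) ** -0.5) + self.beta


class GRUCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng):
        super().__init__()
        self.wz = Linear(n_in + n_hidden, n_hidden, rng)
        self.wr = Linear(n_in + n_hidden, n_hidden, rng)
        self.wh = Linear(n_in + n_hidden, n_hidden, rng)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        xh = concat([x, h], axis=-1)
        z = self.wz(xh).sigmoid()
        r = self.wr(xh).sigmoid()
        h_tilde = self.wh(concat([x, r * h], axis=-1)).tanh()
        return (1.0 - z) * h + z * h_tilde


class GRU(Module):
    """Unidirectional GRU over (N, T, F); returns (outputs, last hidden)."""

    def __init__(self, n_in: int, n_hidden: int, rng):
        super().__init__()
        self.cell = GRUCell(n_in, n_hidden, rng)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h0: Tensor | None = None):
        n, t, _ = x.shape
        h = h0 if h0 is not None else Tensor(np.zeros((n, self.n_hidden)))
        outputs = []
        for step in range(t):
            h = self.cell(x[:, step, :], h)
            outputs.append(h)
        return stack(outputs, axis=1), h


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor):
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        context = context if context is not None else x
        n, t, d = x.shape
        q = self._split(self.wq(x))
        k = self._split(self.wk(context))
        v = self._split(self.wv(context))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(out)


def positional_encoding(t: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal position encodings, shape (t, d_model)."""
    pos = np.arange(t)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc
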