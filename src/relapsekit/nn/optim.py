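"""Adam and RMSprop optimizers for the autodiff parameters."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "RMSprop", "make_optimizer"]


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class RMSprop:
    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8):
        self.params = list(params)
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self.sq = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.sq[i] = self.alpha * self.sq[i] + (1 - self.alpha) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(self.sq[i]) + self.eps)


def make_optimizer(name: str, params, lr: float):
    name = name.lower()
    if name == "adam":
        return Adam(params, lr=lr)
    if name == "rmsprop":
        return RMSprop(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r}")
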