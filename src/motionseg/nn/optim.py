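"""Adam and RMSprop optimizers over flat parameter lists."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        rho: float = 0.9,
        eps: float = 1e-8,
    ) -> None:
        super().__init__(params, lr)
        self.rho, self.eps = rho, eps
        self.sq = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, s in zip(self.params, grads, self.sq):
            s[...] = self.rho * s + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)
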