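"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CosineAnnealingWarmRestarts:
    """lr(t) = lr_min + (lr0 - lr_min)/2 * (1 + cos(pi * t_cur / period)),
    with t_cur reset every `period` epochs (warm restart)."""

    def __init__(self, optimizer: Adam, period: int, lr_min: float = 0.0):
        if period < 1:
            raise ValueError("scheduler period must be >= 1")
        self.optimizer = optimizer
        self.period = period
        self.lr0 = optimizer.lr
        self.lr_min = lr_min

    def step(self, epoch: int):
        t_cur = epoch % self.period
        self.optimizer.lr = (self.lr_min + 0.5 * (self.lr0 - self.lr_min)
                             * (1 + np.cos(np.pi * t_cur / self.period)))
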