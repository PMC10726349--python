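"""Neural-network building blocks: linear, batch-norm, dropout."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    """Base class: parameter bookkeeping only."""

    def parameters(self) -> list:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = centred / (var + self.eps).sqrt()
        else:
            xhat = ((x - self.running_mean)
                    / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an RNG")
        keep = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * keep
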