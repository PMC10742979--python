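"""Adam optimiser and reduce-on-plateau learning-rate scheduling."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    """Adam with bias correction (Kingma & Ba defaults for betas/eps)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored value (lower is better)."""

    def __init__(self, optimizer: Adam, patience: int = 20,
                 factor: float = 0.5, min_delta: float = 0.0):
        self.optimizer = optimizer
        self.patience = int(patience)
        self.factor = float(factor)
        self.min_delta = float(min_delta)
        self.best = np.inf
        self.wait = 0
        self.n_reductions = 0

    def step(self, value: float) -> bool:
        """Record an epoch value; returns True if the rate was reduced."""
        if value < self.best - self.min_delta:
            self.best = value
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            self.optimizer.lr *= self.factor
            self.n_reductions += 1
            self.wait = 0
            return True
        return False
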