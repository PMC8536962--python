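"""Optimisers. Only RMSprop is provided — the protocol trains with it."""

from __future__ import annotations

import numpy as np

__all__ = ["RMSprop"]


class RMSprop:
    """Root-mean-square propagation.

    v <- rho * v + (1 - rho) * g^2 ;  p <- p - lr * g / (sqrt(v) + eps)

    Defaults follow the training protocol: lr = 3e-4, rho = 0.8.
    """

    def __init__(self, params, lr=3e-4, rho=0.8, eps=1e-7):
        self.params = list(params)
        self.lr = float(lr)
        self.rho = float(rho)
        self.eps = float(eps)
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.v):
            if p.grad is None:
                continue
            g = p.grad
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p.data -= self.lr * g / (np.sqrt(v) + self.eps)
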