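"""Stochastic gradient descent with momentum and decoupled-from-loss L2 decay.

Follows the classic heavy-ball update used by mainstream frameworks:

    v <- mu * v + (grad + wd * theta)
    theta <- theta - lr * v

The learning rate may be reassigned between steps (cosine annealing sets it
once per epoch).
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params: list[Parameter] = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
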