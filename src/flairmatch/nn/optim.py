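"""Stochastic gradient descent with (Nesterov) momentum."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class SGD:
    """SGD with classical or Nesterov momentum.

    Update (per parameter ``p`` with gradient ``g``)::

        v <- mu * v + g
        p <- p - lr * (g + mu * v)   # nesterov
        p <- p - lr * v              # classical
    """

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-2,
                 momentum: float = 0.9, nesterov: bool = True):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = dict(params)
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self._velocity = {k: np.zeros_like(p.value) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad[...] = 0.0

    def step(self) -> None:
        mu = self.momentum
        for k, p in self.params.items():
            v = self._velocity[k]
            v *= mu
            v += p.grad
            if self.nesterov and mu > 0:
                p.value -= self.lr * (p.grad + mu * v)
            else:
                p.value -= self.lr * v
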