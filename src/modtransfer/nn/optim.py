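"""ADADELTA optimizer (Zeiler 2012), the single optimizer used here.

Works on any object exposing ``named_params()`` / ``named_grads()``.
Defaults follow the original formulation: decay rho = 0.95, a learning
rate of 1.0 (the method is scale-adaptive) and epsilon = 1e-7.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adadelta"]


class Adadelta:
    def __init__(self, network, lr=1.0, rho=0.95, eps=1e-7):
        self.network = network
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._acc_grad = {k: np.zeros_like(v)
                          for k, v in network.named_params().items()}
        self._acc_delta = {k: np.zeros_like(v)
                           for k, v in network.named_params().items()}

    def step(self):
        params = self.network.named_params()
        grads = self.network.named_grads()
        rho, eps = self.rho, self.eps
        for name, p in params.items():
            g = grads[name]
            eg = self._acc_grad[name]
            ed = self._acc_delta[name]
            eg *= rho
            eg += (1 - rho) * g * g
            delta = np.sqrt(ed + eps) / np.sqrt(eg + eps) * g
            ed *= rho
            ed += (1 - rho) * delta * delta
            p -= self.lr * delta
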