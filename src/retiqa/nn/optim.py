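"""Adam optimiser over the network's named leaf parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, network, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.network = network
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        for name, leaf in network.leaves():
            for k, p in leaf.params.items():
                key = f"{name}.{k}"
                self._m[key] = np.zeros_like(p)
                self._v[key] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, leaf in self.network.leaves():
            for k, p in leaf.params.items():
                key = f"{name}.{k}"
                g = leaf.grads[k]
                m = self._m[key]
                v = self._v[key]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
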