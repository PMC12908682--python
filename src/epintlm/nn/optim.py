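"""Adam optimizer with L2 weight decay (coupled, classic Adam style)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = {id(p): np.zeros_like(p.data) for p in self.params}
        self._v = {id(p): np.zeros_like(p.data) for p in self.params}
        self._t = {id(p): 0 for p in self.params}

    def add_param(self, p: Tensor) -> None:
        """Register a parameter that joins optimization mid-training
        (e.g. the embedding table after unfreezing)."""
        if id(p) not in self._m:
            self.params.append(p)
            self._m[id(p)] = np.zeros_like(p.data)
            self._v[id(p)] = np.zeros_like(p.data)
            self._t[id(p)] = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        for p in self.params:
            if p.grad is None or not p.requires_grad:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            k = id(p)
            self._t[k] += 1
            t = self._t[k]
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1 ** t)
            vhat = self._v[k] / (1 - b2 ** t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
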