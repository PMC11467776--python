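"""AdamW with decoupled weight decay."""

from __future__ import annotations

import numpy as np

from .config import TrainConfig
from .layers import Param


class AdamW:
    def __init__(self, params: list[Param], cfg: TrainConfig):
        self.params = params
        self.lr = cfg.lr
        self.b1, self.b2 = cfg.betas
        self.eps = cfg.eps
        self.wd = cfg.weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p.value -= self.lr * (
                (m / b1t) / (np.sqrt(v / b2t) + self.eps) + self.wd * p.value
            )
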