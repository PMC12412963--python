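"""SGD with momentum plus the warmup/cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np


class SGD:
    """SGD with classical momentum.

    Weight decay is applied only to parameter groups flagged ``decay=True``
    (convolution kernels); batch-norm affine terms and biases are exempt,
    following common detector-training practice.
    """

    def __init__(self, param_groups, lr=0.01, momentum=0.937, weight_decay=0.0):
        # param_groups: list of dicts {params: [...], decay: bool}
        self.groups = param_groups
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = {}

    def step(self):
        for g in self.groups:
            wd = self.weight_decay if g.get("decay") else 0.0
            for p in g["params"]:
                if p.grad is None:
                    continue
                d = p.grad + wd * p.data
                v = self._v.get(id(p))
                v = self.momentum * v + d if v is not None else d
                self._v[id(p)] = v
                p.data = p.data - self.lr * v

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None


def split_decay_groups(module):
    """Two param groups: conv kernels (decayed) vs 1-D params (not)."""
    decay, no_decay = [], []
    for p in module.parameters():
        (decay if p.data.ndim > 1 else no_decay).append(p)
    return [{"params": decay, "decay": True},
            {"params": no_decay, "decay": False}]


def warmup_cosine_lr(epoch: float, epochs: int, lr0: float, lrf: float = 0.01,
                     warmup_epochs: float = 3.0) -> float:
    """Linear warmup to lr0, then cosine decay to lr0*lrf at the last epoch."""
    if epoch < warmup_epochs and warmup_epochs > 0:
        return lr0 * (0.1 + 0.9 * epoch / warmup_epochs)
    t = (epoch - warmup_epochs) / max(epochs - warmup_epochs, 1e-9)
    t = min(max(t, 0.0), 1.0)
    return lr0 * (lrf + (1 - lrf) * 0.5 * (1 + math.cos(math.pi * t)))
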