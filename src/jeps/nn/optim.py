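"""Adam optimizer and the weighted binary cross-entropy loss."""

from __future__ import annotations

import numpy as np

from .layers import F32, Param


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= F32(self.lr) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def weighted_bce(p: np.ndarray, y: np.ndarray, pos_weight: float = 1.0,
                 eps: float = 1e-7) -> float:
    """Mean binary cross-entropy with positive-class weighting."""
    p = np.clip(p, eps, 1 - eps)
    w = np.where(y == 1, pos_weight, 1.0)
    return float(np.mean(-w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def weighted_bce_grad_logits(p: np.ndarray, y: np.ndarray,
                             pos_weight: float = 1.0) -> np.ndarray:
    """Gradient of the weighted BCE w.r.t. the pre-sigmoid logits.

    Fusing the sigmoid into the loss gradient avoids the unstable
    division by ``p (1 - p)``.
    """
    w = np.where(y == 1, pos_weight, 1.0)
    return (w * (p - y) / p.shape[0]).astype(F32)
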