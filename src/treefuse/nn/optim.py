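"""Adam optimiser, cosine learning-rate schedule and gradient clipping."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "cosine_lr", "clip_grad_norm"]


class Adam:
    """Adam with optional L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(lr0: float, epoch: int, max_epochs: int) -> float:
    """Cosine annealing from ``lr0`` at epoch 0 to 0 at the final epoch."""
    if max_epochs <= 1:
        return lr0
    return 0.5 * lr0 * (1.0 + float(np.cos(np.pi * epoch / (max_epochs - 1))))


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        factor = max_norm / norm
        for g in grads:
            g *= factor
    return norm
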