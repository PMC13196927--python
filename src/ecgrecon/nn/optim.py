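"""Optimizers for the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class AdamW:
    """Adaptive-moment optimizer with decoupled weight decay.

    Parameter update (step t, learning rate eta):

        m <- b1 m + (1-b1) g           v <- b2 v + (1-b2) g^2
        p <- p - eta * ( m_hat / (sqrt(v_hat) + eps) + lambda p )

    with bias-corrected m_hat, v_hat.  Weight decay multiplies the parameter
    directly (decoupled from the gradient), the defining AdamW property.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, max_grad_norm: float | None = None) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if max_grad_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > max_grad_norm:
                scale = max_grad_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = p.data - self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
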