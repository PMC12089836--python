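"""AdamW optimizer with decoupled weight decay."""

from __future__ import annotations

import numpy as np


class AdamW:
    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-4, grad_clip=None):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def _clip(self):
        if self.grad_clip is None:
            return
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad.astype(np.float64) ** 2).sum())
        norm = total ** 0.5
        if norm > self.grad_clip:
            scale = self.grad_clip / (norm + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self):
        self._clip()
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[i], self.v[i]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            denom = np.sqrt(v / bc2)
            denom += self.eps
            p.data -= (self.lr / bc1) * m / denom
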