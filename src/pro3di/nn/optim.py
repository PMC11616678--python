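"""Adam optimizer with optional gradient clipping and linear warmup."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .autograd import Tensor


class Adam:
    def __init__(
        self,
        params: Dict[str, Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: Optional[float] = 1.0,
        warmup_steps: int = 0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.warmup_steps = warmup_steps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def current_lr(self) -> float:
        if self.warmup_steps and self.t < self.warmup_steps:
            return self.lr * (self.t + 1) / self.warmup_steps
        return self.lr

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr()
        if self.clip_norm is not None:
            sq = 0.0
            for p in self.params.values():
                if p.grad is not None:
                    sq += float((p.grad.astype(np.float64) ** 2).sum())
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = np.float32(self.clip_norm / (norm + 1e-12))
                for p in self.params.values():
                    if p.grad is not None:
                        p.grad *= scale
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
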