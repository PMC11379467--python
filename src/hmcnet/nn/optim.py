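"""Adam optimizer with optional linear warm-up and exponential decay."""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        params: List[Tuple[str, np.ndarray, np.ndarray]],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        warmup_steps: int = 0,
        decay: float = 1.0,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.warmup_steps = warmup_steps
        self.decay = decay
        self.t = 0
        self.m = [np.zeros_like(w) for _, w, _ in params]
        self.v = [np.zeros_like(w) for _, w, _ in params]

    def current_lr(self) -> float:
        lr = self.lr * self.decay ** self.t
        if self.warmup_steps and self.t < self.warmup_steps:
            lr *= (self.t + 1) / self.warmup_steps
        return lr

    def step(self) -> None:
        lr = self.current_lr()
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for (_, w, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            w -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
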