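"""Optimizers, gradient clipping, and learning-rate scheduling."""
from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "clip_grad_norm", "ReduceLROnPlateau", "global_grad_norm"]


def global_grad_norm(params: list[Tensor]) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad * p.grad))
    return float(np.sqrt(total))


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``.

    Returns the pre-clip norm.  Direction is preserved when scaling occurs;
    zero gradients pass through untouched.  A non-finite gradient raises,
    naming the offending parameter.
    """
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    for i, p in enumerate(params):
        if p.grad is not None and not np.all(np.isfinite(p.grad)):
            name = p.name or f"parameter[{i}]"
            raise FloatingPointError(f"non-finite gradient in {name}")
    norm = global_grad_norm(params)
    if norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer lr after ``patience`` epochs without
    improvement of the monitored metric (minimized)."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 10, eps: float = 0.0):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.eps = eps
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> None:
        if metric < self.best - self.eps:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr *= self.factor
                self.bad_epochs = 0
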