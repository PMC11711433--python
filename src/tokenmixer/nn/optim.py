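"""Optimisers and loss functions."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import Parameter

__all__ = ["Adam", "binary_cross_entropy", "categorical_cross_entropy",
           "softmax_cross_entropy"]


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits) against one-hot labels.

    Computed as logsumexp(logits) - logits[label] for numerical stability.
    """
    z = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - lse
    nll = -(logp * Tensor(onehot.astype(np.float32))).sum(axis=-1)
    return nll.mean()


def categorical_cross_entropy(probs: Tensor, onehot: np.ndarray,
                              eps: float = 1e-7) -> Tensor:
    """Mean cross-entropy against probabilities already summing to one."""
    clipped = probs * (1 - 2 * eps) + eps
    return -(clipped.log() * Tensor(onehot.astype(np.float32))).sum(axis=-1).mean()


def binary_cross_entropy(probs: Tensor, y: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy for a (B,) or (B, 1) vector of probabilities."""
    y = np.asarray(y, dtype=np.float32).reshape(probs.shape)
    p = probs * (1 - 2 * eps) + eps
    one = Tensor(np.ones_like(p.data))
    return -((Tensor(y) * p.log()) + ((one - Tensor(y)) * (one - p).log())).mean()
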