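"""Neural-network building blocks on top of the autograd core.

Conventions follow the channels-last (B, H, W, C) layout throughout; token
sequences are (B, T, D).  Weight initialisation is Glorot-uniform from a
caller-supplied :class:`numpy.random.Generator`, so a built model is fully
determined by its configuration and seed.

``same``-padded convolutions are implemented as sums of spatially shifted
pointwise products/matmuls: for a k x k kernel the input is shifted k^2 times
and each shift contributes one (C_in -> C_out) matmul.  For the small kernels
used here (3x3) this is efficient in numpy and inherits its gradient from the
autograd primitives, with zero padding at the borders.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor

__all__ = [
    "Parameter", "Module", "Dense", "Conv2DSame", "DepthwiseConv2DSame",
    "StridedPatchConv", "BatchNorm", "LayerNorm", "InputStandardization",
    "PositionalEmbedding", "Dropout", "MultiHeadAttention", "GELU", "Sigmoid",
]


class Parameter(Tensor):
    """A tensor registered in a module's inventory.

    ``trainable=False`` marks arrays that belong to the model state but are
    not optimised by gradient descent (batch-norm moving statistics, input
    standardisation statistics).  Both kinds appear in the parameter
    inventory; only trainable ones receive gradients.
    """

    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=trainable)
        self.trainable = trainable


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Minimal module container with named parameter discovery."""

    training: bool = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}[{i}]")
                    elif isinstance(item, Parameter):
                        yield f"{full}[{i}]", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(mode)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 use_bias: bool = True):
        self.weight = Parameter(glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if use_bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2DSame(Module):
    """k x k convolution, stride 1, zero ('same') padding, channels-last."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, use_bias: bool = True):
        if kernel % 2 != 1:
            raise ValueError("same-padded convolution requires an odd kernel")
        self.kernel = kernel
        fan_in = kernel * kernel * in_ch
        self.weight = Parameter(
            glorot_uniform(rng, (kernel, kernel, in_ch, out_ch), fan_in, out_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if use_bias else None

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        r = k // 2
        y = None
        for i in range(k):
            for j in range(k):
                tap = x.shift2d(i - r, j - r) @ self.weight.reshape(
                    k * k, *self.weight.shape[2:])[i * k + j]
                y = tap if y is None else y + tap
        if self.bias is not None:
            y = y + self.bias
        return y


class DepthwiseConv2DSame(Module):
    """k x k depthwise convolution (one spatial filter per channel)."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 use_bias: bool = True):
        if kernel % 2 != 1:
            raise ValueError("same-padded convolution requires an odd kernel")
        self.kernel = kernel
        fan = kernel * kernel
        self.weight = Parameter(
            glorot_uniform(rng, (kernel, kernel, channels), fan, fan))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if use_bias else None

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        r = k // 2
        w = self.weight.reshape(k * k, self.weight.shape[2])
        y = None
        for i in range(k):
            for j in range(k):
                tap = x.shift2d(i - r, j - r) * w[i * k + j]
                y = tap if y is None else y + tap
        if self.bias is not None:
            y = y + self.bias
        return y


class StridedPatchConv(Module):
    """Convolution with kernel = stride = p (a patch embedding).

    Equivalent to cutting the image into non-overlapping p x p patches and
    applying one dense layer to each flattened patch.
    """

    def __init__(self, in_ch: int, out_ch: int, patch: int,
                 rng: np.random.Generator, use_bias: bool = True):
        self.patch = patch
        self.in_ch = in_ch
        fan_in = patch * patch * in_ch
        self.weight = Parameter(
            glorot_uniform(rng, (fan_in, out_ch), fan_in, out_ch))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if use_bias else None

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        p = self.patch
        if h % p or w % p:
            raise ValueError(f"patch size {p} does not divide input {h}x{w}")
        x = x.reshape(b, h // p, p, w // p, p, c)
        x = x.transpose(0, 1, 3, 2, 4, 5)
        x = x.reshape(b, h // p, w // p, p * p * c)
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm(Module):
    """Batch normalisation over all axes except the trailing channel axis."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.moving_mean = Parameter(np.zeros(channels, dtype=np.float32),
                                     trainable=False)
        self.moving_var = Parameter(np.ones(channels, dtype=np.float32),
                                    trainable=False)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes)
            centered = x - mean
            var = (centered * centered).mean(axis=axes)
            m = self.momentum
            self.moving_mean.data = (m * self.moving_mean.data
                                     + (1 - m) * mean.data).astype(np.float32)
            self.moving_var.data = (m * self.moving_var.data
                                    + (1 - m) * var.data).astype(np.float32)
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.moving_mean.data)) * Tensor(
                1.0 / np.sqrt(self.moving_var.data + self.eps))
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class InputStandardization(Module):
    """Per-channel standardisation with statistics adapted from data.

    Holds mean (C), variance (C) and a sample count (1) as non-trainable
    state - 7 values for RGB input - and maps x to (x - mean) / std.
    ``adapt`` accumulates statistics over one or more batches.
    """

    def __init__(self, channels: int = 3, eps: float = 1e-7):
        self.mean = Parameter(np.zeros(channels, dtype=np.float32), trainable=False)
        self.var = Parameter(np.ones(channels, dtype=np.float32), trainable=False)
        self.count = Parameter(np.zeros(1, dtype=np.float32), trainable=False)
        self.eps = eps

    def adapt(self, batch: np.ndarray) -> None:
        flat = np.asarray(batch, dtype=np.float64).reshape(-1, self.mean.data.shape[0])
        n_new = flat.shape[0]
        n_old = float(self.count.data[0])
        mean_new = flat.mean(axis=0)
        var_new = flat.var(axis=0)
        if n_old == 0:
            mean, var = mean_new, var_new
        else:  # Chan et al. pooled-moment update
            mean_old = self.mean.data.astype(np.float64)
            var_old = self.var.data.astype(np.float64)
            n = n_old + n_new
            delta = mean_new - mean_old
            mean = mean_old + delta * n_new / n
            var = (var_old * n_old + var_new * n_new
                   + delta ** 2 * n_old * n_new / n) / n
        self.mean.data = mean.astype(np.float32)
        self.var.data = var.astype(np.float32)
        self.count.data = np.array([n_old + n_new], dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        scale = 1.0 / np.sqrt(self.var.data + self.eps)
        return (x - Tensor(self.mean.data)) * Tensor(scale.astype(np.float32))


class PositionalEmbedding(Module):
    """Learned additive position embedding for a fixed-length token sequence."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.embedding = Parameter(
            rng.uniform(-0.05, 0.05, size=(n_tokens, dim)).astype(np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x + self.embedding


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self._rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


def scaled_dot_product_attention(q: Tensor, k: Tensor, v: Tensor,
                                 d_k: int | None = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_K)) V over the last two axes (batched)."""
    if d_k is None:
        d_k = q.shape[-1]
    if d_k <= 0:
        raise ValueError("key dimension must be positive")
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) \
        * (1.0 / math.sqrt(d_k))
    return scores.softmax(axis=-1) @ v


class MultiHeadAttention(Module):
    """Multi-head self-attention with per-head query/key/value projections.

    Each of Q, K, V is projected from ``dim`` to ``n_heads * key_dim``; the
    per-head attention outputs are concatenated and projected back to ``dim``.
    ``key_dim`` defaults to ``dim`` (full-width heads).
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 key_dim: int | None = None, dropout: float = 0.0):
        if n_heads <= 0:
            raise ValueError("n_heads must be positive")
        key_dim = dim if key_dim is None else key_dim
        inner = n_heads * key_dim
        self.n_heads = n_heads
        self.key_dim = key_dim
        self.wq = Dense(dim, inner, rng)
        self.wk = Dense(dim, inner, rng)
        self.wv = Dense(dim, inner, rng)
        self.wo = Dense(inner, dim, rng)
        self.drop = Dropout(dropout, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.key_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        heads = scaled_dot_product_attention(q, k, v, self.key_dim)
        merged = heads.transpose(0, 2, 1, 3).reshape(b, t, self.n_heads * self.key_dim)
        return self.drop(self.wo(merged))
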