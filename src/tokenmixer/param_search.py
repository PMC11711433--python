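"""Closed-form parameter accounting and the configuration constraint search.

The published model descriptions pin the patchification (224 / 14), the ViT
depth (8) and head count (4), and the four total parameter counts - but not
the latent width, MLP widths, token count or ConvMixer geometry.  This
module provides exact closed-form totals for each architecture family as a
function of its free hyperparameters, plus a small grid-search helper; the
shipped defaults in :mod:`tokenmixer.architectures` are the unique
structurally valid configurations (residual-compatible MLP widths, round
head widths) whose totals equal the published figures exactly.

Totals count the full parameter inventory: trainable weights and biases,
layer/batch-norm scale and shift, positional embeddings, batch-norm moving
statistics and the input-standardisation statistics (mean, variance and
sample count - 7 values for RGB), matching what framework model summaries
report as the total.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

from .architectures import (ConvMixerConfig, TokenLearnerConfig,
                            TokenMixerConfig, ViTConfig)

__all__ = [
    "dense_params", "conv_params", "depthwise_params", "batchnorm_params",
    "layernorm_params", "mha_params", "vit_total", "tokenlearner_total",
    "tokenmixer_total", "convmixer_total", "grid_search", "frozen_totals",
]

INPUT_NORM_PARAMS = 7  # per-channel mean (3) + variance (3) + sample count (1)


def dense_params(d_in: int, d_out: int, bias: bool = True) -> int:
    return d_in * d_out + (d_out if bias else 0)


def conv_params(c_in: int, c_out: int, k: int, bias: bool = True) -> int:
    return k * k * c_in * c_out + (c_out if bias else 0)


def depthwise_params(c: int, k: int, bias: bool = True) -> int:
    return k * k * c + (c if bias else 0)


def batchnorm_params(c: int) -> int:
    return 4 * c  # scale + shift (trainable) + moving mean/var (statistics)


def layernorm_params(d: int) -> int:
    return 2 * d


def mha_params(d: int, heads: int, key_dim: int) -> int:
    inner = heads * key_dim
    return 3 * dense_params(d, inner) + dense_params(inner, d)


def _encoder_block(d: int, heads: int, key_dim: int,
                   mlp_units: Sequence[int]) -> int:
    total = 2 * layernorm_params(d) + mha_params(d, heads, key_dim)
    d_in = d
    for u in mlp_units:
        total += dense_params(d_in, u)
        d_in = u
    return total


def _head(d_in: int, units: Sequence[int], n_out: int) -> int:
    total = 0
    for u in units:
        total += dense_params(d_in, u)
        d_in = u
    return total + dense_params(d_in, n_out)


def vit_total(cfg: ViTConfig) -> int:
    D, N = cfg.latent_dim, cfg.n_patches
    patch_dim = cfg.patch_size ** 2 * 3
    total = (INPUT_NORM_PARAMS if cfg.input_norm else 0)
    total += dense_params(patch_dim, D) + N * D
    total += cfg.layers * _encoder_block(D, cfg.heads, cfg.key_dim, cfg.mlp_units)
    total += layernorm_params(D)
    total += _head(N * D, cfg.head_units, cfg.n_classes)
    return total


def _token_model_total(cfg: TokenLearnerConfig, depthwise_kernel: int | None) -> int:
    D, N, S = cfg.embed_dim, cfg.n_patches, cfg.n_tokens
    patch_dim = cfg.patch_size ** 2 * 3
    total = (INPUT_NORM_PARAMS if cfg.input_norm else 0)
    total += dense_params(patch_dim, D) + N * D
    total += layernorm_params(D)  # tokenizer pre-norm
    if depthwise_kernel is not None:
        total += depthwise_params(D, depthwise_kernel) + batchnorm_params(D)
    c_in = D
    for _ in range(cfg.map_layers):
        total += conv_params(c_in, S, cfg.map_kernel, bias=False)
        c_in = S
    total += cfg.layers * _encoder_block(D, cfg.heads, cfg.key_dim, cfg.mlp_units)
    total += layernorm_params(D)
    total += _head(S * D, cfg.head_units, cfg.n_classes)
    return total


def tokenlearner_total(cfg: TokenLearnerConfig) -> int:
    return _token_model_total(cfg, None)


def tokenmixer_total(cfg: TokenMixerConfig) -> int:
    return _token_model_total(cfg, cfg.depthwise_kernel)


def convmixer_total(cfg: ConvMixerConfig) -> int:
    h = cfg.h
    total = conv_params(3, h, cfg.p) + batchnorm_params(h)
    total += cfg.depth * (depthwise_params(h, cfg.kernel) + batchnorm_params(h)
                          + dense_params(h, h) + batchnorm_params(h))
    total += dense_params(h, cfg.n_classes)
    return total


def grid_search(count_fn, make_cfg, target: int,
                grid: dict[str, Iterable]) -> Iterator[dict]:
    """Yield every grid point whose closed-form total equals ``target``.

    ``make_cfg(**point)`` builds the candidate config; points that raise
    ``ValueError``/``TypeError`` (structurally invalid combinations) are
    skipped.
    """
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        try:
            cfg = make_cfg(**point)
            if count_fn(cfg) == target:
                yield point
        except (ValueError, TypeError):
            continue


PUBLISHED_TOTALS = {
    "vit": 36_376_521,
    "convmixer": 577_282,
    "tokenlearner": 1_402_169,
    "tokenmixer": 1_403_961,
}


def frozen_totals() -> dict[str, int]:
    """Closed-form totals of the shipped default configurations."""
    return {
        "vit": vit_total(ViTConfig()),
        "convmixer": convmixer_total(ConvMixerConfig()),
        "tokenlearner": tokenlearner_total(TokenLearnerConfig()),
        "tokenmixer": tokenmixer_total(TokenMixerConfig()),
    }
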