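"""The four model families: ViT, TokenLearner, ConvMixer and TokenMixer.

All models classify 224 x 224 x 3 histology images (channels-last, values in
[0, 1]) into 2 coarse classes or 8 tumour subtypes.  The transformer models
share one patchification scheme (non-overlapping 14 x 14 patches, N = HW/P^2)
and one pre-norm encoder block; they differ in how the token sequence is
formed:

* ViT attends over all N = 256 embedded patches;
* TokenLearner collapses the embedded patch grid to S = 4 adaptive tokens,
  each the spatially averaged Hadamard product of the grid with a learned
  attention map (four stacked 3x3 convolutions generate the maps);
* TokenMixer additionally mixes the embedded grid with a depthwise 3x3
  convolution + batch normalisation before the maps are generated;
* ConvMixer is all-convolutional: a strided patch-embedding stem followed by
  depth blocks of depthwise (spatial) and pointwise (channel) mixing.

Default configurations are frozen by a constraint search that reproduces the
published parameter totals exactly (see :mod:`tokenmixer.param_search`);
hyperparameters that the published tables pin directly (image size 224,
patch 14, ViT depth 8 and 4 heads) keep those values.  Parameter totals are
counted over the full inventory - trainable weights plus normalisation
statistics - which is what framework model summaries print.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "PatchGrid", "ViTConfig", "TokenLearnerConfig", "TokenMixerConfig",
    "ConvMixerConfig", "ModelHandle",
    "compute_num_patches", "extract_patches", "reassemble_patches",
    "scaled_dot_attention", "multi_head_attention", "token_learner_tokenize",
    "attention_map_tokenizer",
    "build_vit", "build_tokenlearner_model", "build_convmixer", "build_tokenmixer",
    "build_model", "parameter_inventory", "count_parameters",
    "count_trainable_parameters",
]


# --------------------------------------------------------------------------- #
# patchification
# --------------------------------------------------------------------------- #

@dataclass
class PatchGrid:
    """An image decomposed into N = HW/P^2 flattened non-overlapping patches."""

    H: int
    W: int
    C: int
    P: int
    N: int
    patches: np.ndarray  # (N, P*P*C), row-major grid order


def compute_num_patches(H: int, W: int, P: int) -> int:
    """Number of non-overlapping P x P patches tiling an H x W image."""
    if P <= 0 or H % P or W % P:
        raise ValueError(f"patch size {P} must divide image dims {H}x{W}")
    return (H * W) // (P * P)


def extract_patches(image: np.ndarray, P: int) -> PatchGrid:
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("expected a rank-3 (H, W, C) image")
    H, W, C = image.shape
    N = compute_num_patches(H, W, P)
    patches = (image.reshape(H // P, P, W // P, P, C)
               .transpose(0, 2, 1, 3, 4)
               .reshape(N, P * P * C))
    return PatchGrid(H=H, W=W, C=C, P=P, N=N, patches=patches)


def reassemble_patches(grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`extract_patches` (exact)."""
    P, H, W, C = grid.P, grid.H, grid.W, grid.C
    return (grid.patches.reshape(H // P, W // P, P, P, C)
            .transpose(0, 2, 1, 3, 4)
            .reshape(H, W, C))


# --------------------------------------------------------------------------- #
# attention primitives (numpy-facing)
# --------------------------------------------------------------------------- #

def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                         d_k: int | None = None) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_K)) V.

    ``d_k`` defaults to the trailing dimension of K.  Rows of the output are
    convex combinations of the rows of V.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if d_k is None:
        d_k = K.shape[-1]
    if d_k <= 0:
        raise ValueError("key dimension must be positive")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


def multi_head_attention(X: np.ndarray, n_heads: int, key_dim: int | None = None,
                         seed: int = 0) -> np.ndarray:
    """Apply a freshly initialised multi-head self-attention layer to X.

    Convenience functional wrapper; for trained models the
    :class:`tokenmixer.nn.MultiHeadAttention` module is used directly.
    Output shape equals input shape (tokens x D).
    """
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
        squeeze = True
    else:
        squeeze = False
    rng = np.random.default_rng(seed)
    mha = nn.MultiHeadAttention(X.shape[-1], n_heads, rng, key_dim=key_dim)
    mha.set_training(False)
    out = mha(Tensor(X)).numpy()
    return out[0] if squeeze else out


def token_learner_tokenize(X_t: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Adaptive tokenization: z_i = GlobalAvgPool(X_t (.) gamma(alpha_i)).

    ``X_t`` is (H, W, C); ``alpha`` holds S spatial maps (S, H, W), already
    passed through a bounded activation.  gamma broadcasts each map over the
    channel axis; spatial global average pooling reduces to an (S, C) token
    matrix.
    """
    X_t = np.asarray(X_t, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.ndim != 3 or alpha.shape[0] <= 0:
        raise ValueError("alpha must be (S, H, W) with S >= 1")
    if alpha.shape[1:] != X_t.shape[:2]:
        raise ValueError("attention maps must match the spatial dims of X_t")
    return (X_t[None] * alpha[..., None]).mean(axis=(1, 2))


# --------------------------------------------------------------------------- #
# configurations (defaults frozen by the parameter-count constraint search)
# --------------------------------------------------------------------------- #

@dataclass
class ViTConfig:
    image_size: int = 224
    patch_size: int = 14
    layers: int = 8
    heads: int = 4
    key_dim: int = 64          # full-width heads, as in the reference layout
    latent_dim: int = 64
    mlp_units: tuple[int, ...] = (128, 64)     # (2D, D)
    head_units: tuple[int, ...] = (2048, 1024)
    dropout: float = 0.1
    head_dropout: float = 0.5
    n_classes: int = 2
    input_norm: bool = True

    @property
    def n_patches(self) -> int:
        return compute_num_patches(self.image_size, self.image_size, self.patch_size)


@dataclass
class TokenLearnerConfig:
    image_size: int = 224
    patch_size: int = 14
    embed_dim: int = 128
    n_tokens: int = 4          # S, one per map-generating convolution filter
    map_layers: int = 4
    map_kernel: int = 3
    layers: int = 6
    heads: int = 4
    key_dim: int = 64
    mlp_units: tuple[int, ...] = (128,)        # (D,)
    head_units: tuple[int, ...] = (512, 256)
    dropout: float = 0.1
    head_dropout: float = 0.5
    n_classes: int = 2
    input_norm: bool = True

    @property
    def n_patches(self) -> int:
        return compute_num_patches(self.image_size, self.image_size, self.patch_size)

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size


@dataclass
class TokenMixerConfig(TokenLearnerConfig):
    depthwise_kernel: int = 3


@dataclass
class ConvMixerConfig:
    image_size: int = 224
    h: int = 256               # embedding width
    p: int = 4                 # stem patch size (kernel = stride = p)
    depth: int = 8
    kernel: int = 3            # depthwise kernel side
    n_classes: int = 2


@dataclass
class ModelHandle:
    """A built network plus its config and parameter inventory."""

    name: str
    model: nn.Module
    config: object
    inventory: list[tuple[str, int, bool]] = field(repr=False)

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        self.model.set_training(False)
        return self.model(Tensor(np.asarray(images, dtype=np.float32))).numpy()

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities; (B,) for a 1-unit sigmoid head, else (B, K)."""
        logits = self.predict_logits(images)
        if logits.shape[-1] == 1:
            return 1.0 / (1.0 + np.exp(-logits[:, 0]))
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    @property
    def n_outputs(self) -> int:
        return int(getattr(self.config, "n_classes"))

    def inventory_total(self, trainable_only: bool = False) -> int:
        return sum(c for _, c, t in self.inventory if t or not trainable_only)


# --------------------------------------------------------------------------- #
# shared submodules
# --------------------------------------------------------------------------- #

class _EncoderBlock(nn.Module):
    """Pre-norm transformer block: LN -> MHA -> add, LN -> MLP(GELU) -> add."""

    def __init__(self, dim: int, heads: int, key_dim: int,
                 mlp_units: Sequence[int], dropout: float,
                 rng: np.random.Generator):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = nn.MultiHeadAttention(dim, heads, rng, key_dim=key_dim,
                                          dropout=dropout)
        self.norm2 = nn.LayerNorm(dim)
        if mlp_units and mlp_units[-1] != dim:
            raise ValueError("residual MLP must end at the token dimension")
        self.mlp = []
        d_in = dim
        for u in mlp_units:
            self.mlp.append(nn.Dense(d_in, u, rng))
            d_in = u
        self.drop = nn.Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        h = self.norm2(x)
        for dense in self.mlp:
            h = self.drop(dense(h).gelu())
        return x + h


class _MLPHead(nn.Module):
    def __init__(self, in_dim: int, units: Sequence[int], n_out: int,
                 dropout: float, rng: np.random.Generator):
        self.hidden = []
        d = in_dim
        for u in units:
            self.hidden.append(nn.Dense(d, u, rng))
            d = u
        self.out = nn.Dense(d, n_out, rng)
        self.drop = nn.Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.drop(x)
        for dense in self.hidden:
            x = self.drop(dense(x).gelu())
        return self.out(x)


class _AttentionMapTokenizer(nn.Module):
    """Convolutionally generated spatial attention maps -> S pooled tokens.

    The map network is ``map_layers`` stacked same-padded convolutions with
    ``n_tokens`` filters each and no biases; GELU between layers, sigmoid on
    the last so every map value lies in [0, 1].  A TokenMixer variant first
    mixes the (layer-normalised) grid with a depthwise convolution + batch
    normalisation.  Tokens are the spatial means of the input grid weighted
    by each map (Hadamard product broadcast over channels).
    """

    def __init__(self, channels: int, n_tokens: int, map_layers: int,
                 map_kernel: int, rng: np.random.Generator,
                 depthwise_kernel: int | None = None):
        if n_tokens <= 0:
            raise ValueError("token count S must be positive")
        self.norm = nn.LayerNorm(channels)
        if depthwise_kernel is not None:
            self.depthwise = nn.DepthwiseConv2DSame(channels, depthwise_kernel, rng)
            self.bn = nn.BatchNorm(channels)
        else:
            self.depthwise = None
            self.bn = None
        self.convs = []
        c_in = channels
        for _ in range(map_layers):
            self.convs.append(nn.Conv2DSame(c_in, n_tokens, map_kernel, rng,
                                            use_bias=False))
            c_in = n_tokens
        self.n_tokens = n_tokens

    def forward(self, x: Tensor) -> Tensor:
        """(B, H, W, C) grid -> (B, S, C) tokens."""
        h = self.norm(x)
        if self.depthwise is not None:
            h = self.bn(self.depthwise(h))
        for conv in self.convs[:-1]:
            h = conv(h).gelu()
        alpha = self.convs[-1](h).sigmoid()           # (B, H, W, S)
        b, H, W, S = alpha.shape
        maps = alpha.transpose(0, 3, 1, 2).reshape(b, S, H, W, 1)
        x_b = x.reshape(b, 1, H, W, x.shape[-1])
        return (x_b * maps).mean(axis=(2, 3))         # (B, S, C)


def attention_map_tokenizer(patch_grid: np.ndarray, config: TokenMixerConfig,
                            seed: int = 0) -> np.ndarray:
    """Functional TokenMixer tokenizer on an embedded (B, H, W, C) grid."""
    rng = np.random.default_rng(seed)
    tok = _AttentionMapTokenizer(patch_grid.shape[-1], config.n_tokens,
                                 config.map_layers, config.map_kernel, rng,
                                 depthwise_kernel=config.depthwise_kernel)
    tok.set_training(False)
    return tok(Tensor(np.asarray(patch_grid, dtype=np.float32))).numpy()


# --------------------------------------------------------------------------- #
# the four classifiers
# --------------------------------------------------------------------------- #

class _ViT(nn.Module):
    def __init__(self, cfg: ViTConfig, rng: np.random.Generator):
        D = cfg.latent_dim
        self.input_norm = nn.InputStandardization(3) if cfg.input_norm else None
        self.embed = nn.StridedPatchConv(3, D, cfg.patch_size, rng)
        self.pos = nn.PositionalEmbedding(cfg.n_patches, D, rng)
        self.blocks = [
            _EncoderBlock(D, cfg.heads, cfg.key_dim, cfg.mlp_units, cfg.dropout, rng)
            for _ in range(cfg.layers)
        ]
        self.norm = nn.LayerNorm(D)
        self.head = _MLPHead(cfg.n_patches * D, cfg.head_units, cfg.n_classes,
                             cfg.head_dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.input_norm is not None:
            x = self.input_norm(x)
        g = self.embed(x)                              # (B, 16, 16, D)
        b, gh, gw, D = g.shape
        t = self.pos(g.reshape(b, gh * gw, D))
        for block in self.blocks:
            t = block(t)
        t = self.norm(t)
        return self.head(t.reshape(b, gh * gw * D))


class _TokenModel(nn.Module):
    """Shared body of TokenLearner (no depthwise mixing) and TokenMixer."""

    def __init__(self, cfg: TokenLearnerConfig, rng: np.random.Generator,
                 depthwise_kernel: int | None):
        D = cfg.embed_dim
        self.input_norm = nn.InputStandardization(3) if cfg.input_norm else None
        self.embed = nn.StridedPatchConv(3, D, cfg.patch_size, rng)
        self.pos = nn.PositionalEmbedding(cfg.n_patches, D, rng)
        self.tokenizer = _AttentionMapTokenizer(
            D, cfg.n_tokens, cfg.map_layers, cfg.map_kernel, rng,
            depthwise_kernel=depthwise_kernel)
        self.blocks = [
            _EncoderBlock(D, cfg.heads, cfg.key_dim, cfg.mlp_units, cfg.dropout, rng)
            for _ in range(cfg.layers)
        ]
        self.norm = nn.LayerNorm(D)
        self.head = _MLPHead(cfg.n_tokens * D, cfg.head_units, cfg.n_classes,
                             cfg.head_dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.input_norm is not None:
            x = self.input_norm(x)
        g = self.embed(x)                              # (B, 16, 16, D)
        b, gh, gw, D = g.shape
        g = self.pos(g.reshape(b, gh * gw, D)).reshape(b, gh, gw, D)
        t = self.tokenizer(g)                          # (B, S, D)
        for block in self.blocks:
            t = block(t)
        t = self.norm(t)
        return self.head(t.reshape(b, t.shape[1] * D))


class _ConvMixer(nn.Module):
    def __init__(self, cfg: ConvMixerConfig, rng: np.random.Generator):
        h = cfg.h
        self.stem = nn.StridedPatchConv(3, h, cfg.p, rng)
        self.stem_bn = nn.BatchNorm(h)
        self.depthwise = [nn.DepthwiseConv2DSame(h, cfg.kernel, rng)
                          for _ in range(cfg.depth)]
        self.dw_bn = [nn.BatchNorm(h) for _ in range(cfg.depth)]
        self.pointwise = [nn.Dense(h, h, rng) for _ in range(cfg.depth)]
        self.pw_bn = [nn.BatchNorm(h) for _ in range(cfg.depth)]
        self.head = nn.Dense(h, cfg.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        z = self.stem_bn(self.stem(x).gelu())          # Z0 = BN(sigma(conv))
        for dw, bn1, pw, bn2 in zip(self.depthwise, self.dw_bn,
                                    self.pointwise, self.pw_bn):
            z = bn1(dw(z).gelu() + z)                  # residual inside the BN
            z = bn2(pw(z).gelu())                      # 1x1 channel mixing
        pooled = z.mean(axis=(1, 2))
        return self.head(pooled)


# --------------------------------------------------------------------------- #
# builders and parameter accounting
# --------------------------------------------------------------------------- #

def parameter_inventory(model: nn.Module) -> list[tuple[str, int, bool]]:
    """Per-array (name, element count, trainable) inventory."""
    return [(name, int(np.prod(p.data.shape)), p.trainable)
            for name, p in model.named_parameters()]


def count_parameters(model: nn.Module | ModelHandle) -> int:
    """Full parameter inventory total (trainable + normalisation statistics).

    This is the figure framework model summaries print as the total, and the
    one the published per-model totals correspond to.
    """
    if isinstance(model, ModelHandle):
        return model.inventory_total(trainable_only=False)
    return sum(c for _, c, _ in parameter_inventory(model))


def count_trainable_parameters(model: nn.Module | ModelHandle) -> int:
    """Total over gradient-trained arrays only."""
    if isinstance(model, ModelHandle):
        return model.inventory_total(trainable_only=True)
    return sum(c for _, c, t in parameter_inventory(model) if t)


def _handle(name: str, model: nn.Module, config) -> ModelHandle:
    return ModelHandle(name=name, model=model, config=config,
                       inventory=parameter_inventory(model))


def build_vit(config: ViTConfig | None = None, seed: int = 0) -> ModelHandle:
    config = config or ViTConfig()
    return _handle("vit", _ViT(config, np.random.default_rng(seed)), config)


def build_tokenlearner_model(config: TokenLearnerConfig | None = None,
                             seed: int = 0) -> ModelHandle:
    config = config or TokenLearnerConfig()
    model = _TokenModel(config, np.random.default_rng(seed), depthwise_kernel=None)
    return _handle("tokenlearner", model, config)


def build_tokenmixer(config: TokenMixerConfig | None = None,
                     seed: int = 0) -> ModelHandle:
    config = config or TokenMixerConfig()
    model = _TokenModel(config, np.random.default_rng(seed),
                        depthwise_kernel=config.depthwise_kernel)
    return _handle("tokenmixer", model, config)


def build_convmixer(config: ConvMixerConfig | None = None,
                    n_classes: int | None = None, seed: int = 0) -> ModelHandle:
    config = config or ConvMixerConfig()
    if n_classes is not None:
        config = ConvMixerConfig(**{**config.__dict__, "n_classes": n_classes})
    return _handle("convmixer", _ConvMixer(config, np.random.default_rng(seed)),
                   config)


_BUILDERS = {
    "vit": (build_vit, ViTConfig),
    "tokenlearner": (build_tokenlearner_model, TokenLearnerConfig),
    "tokenmixer": (build_tokenmixer, TokenMixerConfig),
    "convmixer": (build_convmixer, ConvMixerConfig),
}


def build_model(name: str, n_classes: int | None = None, seed: int = 0,
                **overrides) -> ModelHandle:
    """Build any of the four models by name with config overrides."""
    try:
        builder, cfg_cls = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; expected one of {sorted(_BUILDERS)}")
    cfg = cfg_cls(**overrides) if overrides else cfg_cls()
    if n_classes is not None:
        cfg = cfg_cls(**{**cfg.__dict__, "n_classes": n_classes})
    if name == "convmixer":
        return builder(cfg, seed=seed)
    return builder(cfg, seed=seed)
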