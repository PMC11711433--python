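"""Patchification, attention, tokenization and the four model builders."""

import math

import numpy as np
import pytest

from tokenmixer import nn
from tokenmixer.architectures import (
    ConvMixerConfig, TokenLearnerConfig, TokenMixerConfig, ViTConfig,
    _AttentionMapTokenizer, _EncoderBlock, attention_map_tokenizer,
    build_convmixer, build_model, build_tokenlearner_model, build_tokenmixer,
    build_vit, compute_num_patches, count_parameters,
    count_trainable_parameters, extract_patches, multi_head_attention,
    parameter_inventory, reassemble_patches, scaled_dot_attention,
    token_learner_tokenize,
)
from tokenmixer.nn import Tensor
from tokenmixer.synthetic import make_toy_tensors

PUBLISHED = {"vit": 36_376_521, "convmixer": 577_282,
             "tokenlearner": 1_402_169, "tokenmixer": 1_403_961}


class TestPatchification:
    def test_224_by_14_gives_256_patches(self):
        assert compute_num_patches(224, 224, 14) == 256

    def test_single_patch_identity(self):
        assert compute_num_patches(14, 14, 14) == 1
        img = make_toy_tensors((1, 14, 14, 3), seed=0)[0]
        grid = extract_patches(img, 14)
        np.testing.assert_array_equal(grid.patches[0], img.reshape(-1))

    def test_indivisible_patch_errors(self):
        with pytest.raises(ValueError):
            compute_num_patches(224, 224, 15)

    def test_patch_dims_and_roundtrip(self):
        img = make_toy_tensors((1, 224, 224, 3), seed=1)[0]
        grid = extract_patches(img, 14)
        assert grid.patches.shape == (256, 14 * 14 * 3)
        np.testing.assert_array_equal(reassemble_patches(grid), img)

    @pytest.mark.parametrize("h,w,p", [(28, 42, 14), (8, 8, 2), (6, 9, 3)])
    def test_roundtrip_on_assorted_divisible_shapes(self, h, w, p):
        img = make_toy_tensors((1, h, w, 3), seed=2)[0]
        grid = extract_patches(img, p)
        assert grid.N == h * w // p ** 2
        np.testing.assert_array_equal(reassemble_patches(grid), img)


def brute_force_attention(Q, K, V, d_k):
    """Independent scalar-loop reference for softmax(QK^T/sqrt(dK))V."""
    n_q, n_k = len(Q), len(K)
    out = np.zeros((n_q, V.shape[1]))
    for i in range(n_q):
        scores = [sum(Q[i][d] * K[j][d] for d in range(len(Q[i]))) / math.sqrt(d_k)
                  for j in range(n_k)]
        mx = max(scores)
        w = [math.exp(s - mx) for s in scores]
        z = sum(w)
        for j in range(n_k):
            for d in range(V.shape[1]):
                out[i, d] += (w[j] / z) * V[j][d]
    return out


class TestScaledDotAttention:
    def test_single_token_passes_value_through(self):
        out = scaled_dot_attention([[1.0, 0.0]], [[1.0, 0.0]], [[1.0, 0.0]])
        np.testing.assert_allclose(out, [[1.0, 0.0]], atol=1e-12)

    def test_identical_keys_average_the_values(self):
        K = [[0.3, 0.7], [0.3, 0.7], [0.3, 0.7]]
        V = [[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]]
        out = scaled_dot_attention([[5.0, -1.0]], K, V)
        np.testing.assert_allclose(out, [np.mean(V, axis=0)], atol=1e-12)

    def test_two_key_example_matches_hand_computation(self):
        out = scaled_dot_attention([[1.0, 0.0]], [[1.0, 0.0], [0.0, 1.0]],
                                   [[1.0, 0.0], [0.0, 1.0]], d_k=2)
        # scores (1/sqrt2, 0) -> softmax -> (0.6698, 0.3302)
        np.testing.assert_allclose(out, [[0.66983, 0.33017]], atol=1e-4)

    def test_nonpositive_key_dim_errors(self):
        with pytest.raises(ValueError):
            scaled_dot_attention([[1.0]], [[1.0]], [[1.0]], d_k=0)

    def test_outputs_stay_in_convex_hull_of_values(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Q = rng.standard_normal((3, 4))
            K = rng.standard_normal((5, 4))
            V = rng.standard_normal((5, 2))
            out = scaled_dot_attention(Q, K, V)
            assert (out.min(axis=0) >= V.min(axis=0) - 1e-9).all()
            assert (out.max(axis=0) <= V.max(axis=0) + 1e-9).all()


class TestMultiHeadAttention:
    def test_shape_contract(self):
        x = make_toy_tensors((1, 16, 16, 1), seed=3).reshape(1, 256, 1)
        x = np.repeat(x, 64, axis=2).astype(np.float32)
        out = multi_head_attention(x[0], n_heads=4)
        assert out.shape == (256, 64)

    def test_one_head_with_identity_projections_reduces_to_attention(self):
        rng = np.random.default_rng(0)
        D = 4
        mha = nn.MultiHeadAttention(D, 1, rng, key_dim=D)
        for proj in (mha.wq, mha.wk, mha.wv, mha.wo):
            proj.weight.data = np.eye(D, dtype=np.float32)
            proj.bias.data[:] = 0
        x = rng.standard_normal((3, D)).astype(np.float32)
        out = mha(Tensor(x[None])).numpy()[0]
        np.testing.assert_allclose(out, scaled_dot_attention(x, x, x),
                                   atol=1e-6)

    @pytest.mark.parametrize("n_tokens,n_heads", [(2, 1), (3, 2), (4, 2)])
    def test_heads_match_bruteforce_on_projected_tensors(self, n_tokens, n_heads):
        rng = np.random.default_rng(n_tokens * 10 + n_heads)
        D, kd = 6, 3
        mha = nn.MultiHeadAttention(D, n_heads, rng, key_dim=kd)
        x = rng.standard_normal((n_tokens, D)).astype(np.float32)
        q = x @ mha.wq.weight.data + mha.wq.bias.data
        k = x @ mha.wk.weight.data + mha.wk.bias.data
        v = x @ mha.wv.weight.data + mha.wv.bias.data
        heads = []
        for h in range(n_heads):
            sl = slice(h * kd, (h + 1) * kd)
            heads.append(brute_force_attention(q[:, sl], k[:, sl], v[:, sl], kd))
        expected = np.concatenate(heads, axis=1) @ mha.wo.weight.data \
            + mha.wo.bias.data
        out = mha(Tensor(x[None])).numpy()[0]
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_zero_heads_rejected(self):
        with pytest.raises(ValueError):
            nn.MultiHeadAttention(4, 0, np.random.default_rng(0))


class TestTokenLearnerTokenize:
    def test_uniform_maps_equal_global_average_pooling(self):
        x = make_toy_tensors((1, 8, 8, 5), seed=4)[0]
        alpha = np.ones((3, 8, 8))
        z = token_learner_tokenize(x, alpha)
        np.testing.assert_allclose(z, np.tile(x.mean(axis=(0, 1)), (3, 1)),
                                   atol=1e-12)

    def test_one_hot_map_selects_single_pixel_over_hw(self):
        x = make_toy_tensors((1, 4, 6, 3), seed=5)[0]
        alpha = np.zeros((1, 4, 6))
        alpha[0, 2, 3] = 1.0
        z = token_learner_tokenize(x, alpha)
        np.testing.assert_allclose(z[0], x[2, 3, :] / (4 * 6), atol=1e-12)

    def test_shape_contract(self):
        x = make_toy_tensors((1, 32, 32, 16), seed=6)[0]
        alpha = make_toy_tensors((1, 8, 32, 32), seed=7)[0]
        assert token_learner_tokenize(x, alpha).shape == (8, 16)

    def test_empty_map_stack_errors(self):
        with pytest.raises(ValueError):
            token_learner_tokenize(np.zeros((4, 4, 3)), np.zeros((0, 4, 4)))


class TestAttentionMapTokenizer:
    def test_zeroed_map_weights_give_half_pooled_input(self):
        rng = np.random.default_rng(0)
        tok = _AttentionMapTokenizer(8, 4, 4, 3, rng)
        for conv in tok.convs:
            conv.weight.data[:] = 0.0
        tok.norm.gamma.data[:] = 1.0
        x = make_toy_tensors((2, 6, 6, 8), seed=8).astype(np.float32)
        z = tok(Tensor(x)).numpy()
        expected = 0.5 * x.mean(axis=(1, 2))  # sigmoid(0) = 0.5 times the pool
        np.testing.assert_allclose(z, expected[:, None, :].repeat(4, axis=1),
                                   atol=1e-6)

    def test_default_config_emits_four_tokens(self):
        cfg = TokenMixerConfig()
        grid = make_toy_tensors((1, 16, 16, 128), seed=9).astype(np.float32)
        z = attention_map_tokenizer(grid, cfg, seed=0)
        assert z.shape == (1, 4, 128)

    def test_fixed_weights_fixed_input_is_deterministic(self):
        cfg = TokenMixerConfig()
        grid = make_toy_tensors((1, 16, 16, 128), seed=10).astype(np.float32)
        np.testing.assert_array_equal(attention_map_tokenizer(grid, cfg, seed=3),
                                      attention_map_tokenizer(grid, cfg, seed=3))

    def test_nonpositive_token_count_errors(self):
        with pytest.raises(ValueError):
            _AttentionMapTokenizer(8, 0, 4, 3, np.random.default_rng(0))


class TestEncoderBlock:
    def test_zeroed_output_projections_make_block_an_identity(self):
        rng = np.random.default_rng(0)
        block = _EncoderBlock(8, 2, 4, (8,), 0.0, rng)
        block.attn.wo.weight.data[:] = 0
        block.attn.wo.bias.data[:] = 0
        block.mlp[-1].weight.data[:] = 0
        block.mlp[-1].bias.data[:] = 0
        x = make_toy_tensors((2, 5, 8, 1), seed=11)[..., 0].astype(np.float32)
        np.testing.assert_allclose(block(Tensor(x)).numpy(), x, atol=1e-7)

    def test_shape_preserved_and_bit_stable(self):
        rng = np.random.default_rng(1)
        blocks = [_EncoderBlock(8, 2, 4, (16, 8), 0.0, rng) for _ in range(2)]
        for b in blocks:
            b.set_training(False)
        x = make_toy_tensors((2, 5, 8, 1), seed=12)[..., 0].astype(np.float32)

        def run():
            t = Tensor(x)
            for b in blocks:
                t = b(t)
            return t.numpy()

        out1, out2 = run(), run()
        assert out1.shape == x.shape
        np.testing.assert_array_equal(out1, out2)


def gelu_scalar(v):
    return 0.5 * v * (1 + math.erf(v / math.sqrt(2)))


class TestConvMixer:
    def test_stem_shape(self):
        h = build_convmixer(ConvMixerConfig(h=8, p=2, depth=1))
        stem_out = h.model.stem(Tensor(np.zeros((1, 224, 224, 3), np.float32)))
        assert stem_out.shape == (1, 112, 112, 8)

    def test_zero_input_inference_gives_zero_logits(self):
        h = build_convmixer(ConvMixerConfig(image_size=8, h=4, p=2, depth=2))
        out = h.predict_logits(np.zeros((1, 8, 8, 3), np.float32))
        np.testing.assert_allclose(out, 0.0, atol=1e-7)

    def test_stem_single_patch_matches_scalar_oracle(self):
        cfg = ConvMixerConfig(image_size=2, h=3, p=2, depth=1)
        h = build_convmixer(cfg, seed=5)
        h.model.set_training(False)
        h.model.stem_bn.eps = 0.0  # identity statistics, exact oracle
        x = make_toy_tensors((1, 2, 2, 3), seed=13).astype(np.float32)
        z = h.model.stem_bn(h.model.stem(Tensor(x)).gelu())
        w, b = h.model.stem.weight.data, h.model.stem.bias.data
        expected = [gelu_scalar(float(x.reshape(-1) @ w[:, c] + b[c]))
                    for c in range(3)]
        np.testing.assert_allclose(z.numpy().reshape(-1), expected, atol=1e-5)

    def test_block_single_pixel_matches_scalar_oracle(self):
        cfg = ConvMixerConfig(image_size=2, h=1, p=2, depth=1, kernel=3)
        handle = build_convmixer(cfg, seed=6)
        m = handle.model
        for bn in (m.stem_bn, m.dw_bn[0], m.pw_bn[0]):
            bn.eps = 0.0
        m.set_training(False)
        x = make_toy_tensors((1, 2, 2, 3), seed=14).astype(np.float32)
        out = m(Tensor(x)).numpy()
        # scalar re-computation: stem -> depthwise(1x1 spatial: centre tap)
        # -> residual -> pointwise -> head
        z0 = gelu_scalar(float(x.reshape(-1) @ m.stem.weight.data[:, 0]
                               + m.stem.bias.data[0]))
        w_dw = float(m.depthwise[0].weight.data[1, 1, 0])  # centre of 3x3
        b_dw = float(m.depthwise[0].bias.data[0])
        z1 = gelu_scalar(w_dw * z0 + b_dw) + z0
        z2 = gelu_scalar(z1 * float(m.pointwise[0].weight.data[0, 0])
                         + float(m.pointwise[0].bias.data[0]))
        logits = z2 * m.head.weight.data[0] + m.head.bias.data
        np.testing.assert_allclose(out[0], logits, atol=1e-5)

    def test_depth_increment_adds_one_block_of_parameters(self):
        c5 = count_parameters(build_convmixer(ConvMixerConfig(depth=5)))
        c6 = count_parameters(build_convmixer(ConvMixerConfig(depth=6)))
        h, k = 256, 3
        block = (k * k * h + h + 4 * h) + (h * h + h + 4 * h)
        assert c6 - c5 == block


class TestBuilders:
    @pytest.mark.parametrize("name", list(PUBLISHED))
    def test_frozen_configs_reproduce_published_totals(self, name):
        assert count_parameters(build_model(name)) == PUBLISHED[name]

    def test_inventory_total_equals_count(self):
        h = build_tokenmixer()
        assert sum(c for _, c, _ in h.inventory) == count_parameters(h)

    def test_doubling_latent_dim_strictly_increases_vit_count(self):
        base = count_parameters(build_vit(ViTConfig()))
        wide = count_parameters(build_vit(
            ViTConfig(latent_dim=128, mlp_units=(256, 128))))
        assert wide > base

    def test_tokenlearner_sequence_reduced_below_patch_count(self):
        cfg = TokenLearnerConfig()
        assert cfg.n_tokens < cfg.n_patches

    def test_logit_shapes(self):
        x = np.zeros((2, 56, 56, 3), np.float32)
        for name in ("vit", "tokenlearner", "tokenmixer"):
            h = build_model(name, image_size=56)
            assert h.predict_logits(x).shape == (2, 2)
        h = build_convmixer(ConvMixerConfig(image_size=56), n_classes=8)
        assert h.predict_logits(x).shape == (2, 8)

    def test_sigmoid_binary_head_shape(self):
        cfg = TokenMixerConfig(image_size=56, n_classes=1)
        h = build_tokenmixer(cfg)
        p = h.predict_proba(np.zeros((3, 56, 56, 3), np.float32))
        assert p.shape == (3,)
        assert ((p >= 0) & (p <= 1)).all()

    def test_tokenmixer_minus_tokenlearner_is_depthwise_plus_bn(self):
        delta = (count_parameters(build_tokenmixer())
                 - count_parameters(build_tokenlearner_model()))
        k, c = 3, 128
        assert delta == (k * k * c + c) + 4 * c == 1792

    def test_same_config_gives_identical_inventory(self):
        a = build_vit(seed=0).inventory
        b = build_vit(seed=99).inventory
        assert a == b


class TestParameterCounting:
    def test_dense_map_example(self):
        rng = np.random.default_rng(0)
        layer = nn.Dense(588, 64, rng)
        assert sum(int(np.prod(p.data.shape))
                   for _, p in layer.named_parameters()) == 37_696

    def test_batchnorm_trainable_count_is_scale_plus_shift(self):
        bn = nn.BatchNorm(64)
        trainable = sum(int(np.prod(p.data.shape))
                        for _, p in bn.named_parameters() if p.trainable)
        assert trainable == 128

    def test_trainable_versus_full_inventory_on_vit(self):
        h = build_vit()
        # the 7-value input standardisation statistics are the only
        # non-trainable arrays in the ViT
        assert count_parameters(h) - count_trainable_parameters(h) == 7
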