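"""Grouped multi-scale attention: examples, oracle equivalence, cost law."""

import numpy as np
import pytest

from scaleformer.autodiff import Tensor, count_multiplies
from scaleformer.exceptions import ConfigurationError, ShapeError
from scaleformer.gmsa import (GMSAConfig, GroupedMultiScaleAttention,
                              detokenize, gmsa_cost, scaled_dot_attention,
                              split_channels, tokenize)

import oracles


class TestSplitChannels:
    def test_partition_roundtrip_is_identity(self, rng):
        x = Tensor(rng.normal(size=(2, 8, 4, 4)).astype(np.float32))
        parts = split_channels(x, [4, 4])
        assert [p.shape[1] for p in parts] == [4, 4]
        recon = np.concatenate([p.data for p in parts], axis=1)
        assert np.array_equal(recon, x.data)          # bit-exact

    def test_single_group_identity(self, rng):
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        (part,) = split_channels(x, [8])
        assert np.array_equal(part.data, x.data)

    def test_width_mismatch_raises(self, rng):
        x = Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32))
        with pytest.raises(ConfigurationError, match="6.*8"):
            split_channels(x, [3, 3])


class TestTokenize:
    def test_s1_is_global_mean(self, rng):
        x = rng.normal(size=(2, 3, 5, 7)).astype(np.float32)
        tokens = tokenize(Tensor(x), 1)
        assert tokens.shape == (2, 1, 3)
        assert np.allclose(tokens.data[:, 0], x.mean(axis=(2, 3)), atol=1e-6)

    def test_4x4_block_average(self):
        x = np.arange(1, 17, dtype=np.float32).reshape(1, 1, 4, 4)
        tokens = tokenize(Tensor(x), 2)
        assert np.allclose(tokens.data.ravel(), [3.5, 5.5, 11.5, 13.5])

    def test_full_grid_is_pixels_row_major(self, rng):
        x = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        tokens = tokenize(Tensor(x), 3)
        expect = x.reshape(1, 2, 9).transpose(0, 2, 1)
        assert np.allclose(tokens.data, expect, atol=1e-7)

    def test_invalid_grid_raises(self):
        x = Tensor(np.zeros((1, 1, 4, 4), dtype=np.float32))
        with pytest.raises(ConfigurationError):
            tokenize(x, 0)
        with pytest.raises(ShapeError):
            tokenize(x, 5)

    def test_non_divisible_uses_edge_padding(self, rng):
        x = rng.normal(size=(1, 1, 5, 5)).astype(np.float32)
        tokens = tokenize(Tensor(x), 2)
        assert np.allclose(tokens.data, oracles.ref_tokenize(x, 2), atol=1e-6)


class TestDetokenize:
    def test_roundtrip_on_patch_constant_map(self):
        base = np.array([[1., 2.], [3., 4.]], dtype=np.float32)
        x = np.kron(base, np.ones((2, 2), dtype=np.float32))[None, None]
        out = detokenize(tokenize(Tensor(x), 2), 2, 4, 4)
        assert np.array_equal(out.data, x)

    def test_s1_broadcast_constant(self):
        tokens = Tensor(np.full((1, 1, 3), 7.0, dtype=np.float32))
        out = detokenize(tokens, 1, 4, 6)
        assert out.shape == (1, 3, 4, 6)
        assert np.all(out.data == 7.0)

    def test_inverse_of_tokenize_example(self):
        tokens = Tensor(np.array([3.5, 5.5, 11.5, 13.5],
                                 dtype=np.float32).reshape(1, 4, 1))
        out = detokenize(tokens, 2, 4, 4)
        expect = np.kron(np.array([[3.5, 5.5], [11.5, 13.5]]),
                         np.ones((2, 2)))[None, None]
        assert np.allclose(out.data, expect)

    def test_token_count_mismatch_raises(self):
        with pytest.raises(ShapeError):
            detokenize(Tensor(np.zeros((1, 3, 1), dtype=np.float32)), 2, 4, 4)

    def test_crops_padding(self, rng):
        tokens = Tensor(rng.normal(size=(1, 4, 2)).astype(np.float32))
        out = detokenize(tokens, 2, 5, 5)
        assert out.shape == (1, 2, 5, 5)
        assert np.allclose(out.data,
                           oracles.ref_detokenize(tokens.data, 2, 5, 5),
                           atol=1e-6)


class TestScaledDotAttention:
    def test_single_token_returns_value(self, rng):
        q, k, v = (Tensor(rng.normal(size=(2, 1, 4)).astype(np.float32))
                   for _ in range(3))
        out, w = scaled_dot_attention(q, k, v, heads=2, return_weights=True)
        assert np.allclose(w.data, 1.0)
        assert np.allclose(out.data, v.data, atol=1e-6)

    def test_zero_keys_give_uniform_mean(self, rng):
        q = Tensor(rng.normal(size=(1, 5, 4)).astype(np.float32))
        k = Tensor(np.zeros((1, 5, 4), dtype=np.float32))
        v = Tensor(rng.normal(size=(1, 5, 4)).astype(np.float32))
        out, w = scaled_dot_attention(q, k, v, return_weights=True)
        assert np.allclose(w.data, 0.2, atol=1e-6)
        assert np.allclose(out.data, v.data.mean(axis=1, keepdims=True),
                           atol=1e-6)

    def test_hand_softmax_example(self):
        # K = [0, ln3 * sqrt(d)] with d=1 -> logits [0, ln3] -> [0.25, 0.75]
        q = Tensor(np.ones((1, 2, 1), dtype=np.float32))
        k = Tensor(np.array([[[0.0], [np.log(3.0)]]], dtype=np.float32))
        v = Tensor(np.array([[[0.0], [1.0]]], dtype=np.float32))
        out, w = scaled_dot_attention(q, k, v, return_weights=True)
        assert np.allclose(w.data.squeeze(), [[0.25, 0.75], [0.25, 0.75]],
                           atol=1e-6)
        assert np.allclose(out.data.squeeze(), [0.75, 0.75], atol=1e-6)

    def test_rows_are_convex_combinations_100_trials(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, h = int(rng.integers(1, 9)), int(rng.choice([1, 2]))
            d = 2 * h
            q, k, v = (Tensor(rng.normal(size=(1, n, d)).astype(np.float32))
                       for _ in range(3))
            _, w = scaled_dot_attention(q, k, v, heads=h, return_weights=True)
            assert np.allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)
            assert np.all(w.data >= 0)

    def test_indivisible_heads_raise(self):
        t = Tensor(np.zeros((1, 2, 3), dtype=np.float32))
        with pytest.raises(ConfigurationError):
            scaled_dot_attention(t, t, t, heads=2)


class TestGMSAForward:
    def test_zero_weights_give_zero_map(self, rng):
        m = GroupedMultiScaleAttention(GMSAConfig(8, [1, 2]),
                                       np.random.default_rng(0))
        for p in m.parameters():
            p.data[...] = 0.0
        x = Tensor(rng.normal(size=(2, 8, 4, 4)).astype(np.float32))
        out = m(x)
        assert out.shape == x.shape
        assert np.all(out.data == 0.0)

    def test_table_config_token_counts(self):
        cost = gmsa_cost(GMSAConfig(8, [1, 2, 4, 7]), 56)
        assert [g["tokens"] for g in cost["groups"]] == [1, 4, 16, 49]

    @pytest.mark.parametrize("hw", [4, 8])
    @pytest.mark.parametrize("G,scales", [
        (1, [1]), (1, [2]), (1, [4]),
        (2, [1, 1]), (2, [2, 2]), (2, [4, 4]), (2, [1, 2]), (2, [2, 4]),
        (4, [1, 1, 1, 1]), (4, [2, 2, 2, 2]), (4, [4, 4, 4, 4]),
        (4, [1, 2, 4, 4]),
    ])
    def test_matches_bruteforce_oracle(self, hw, G, scales):
        rng = np.random.default_rng(hw * 100 + G)
        c = 4 * G
        m = GroupedMultiScaleAttention(GMSAConfig(c, scales),
                                      np.random.default_rng(99))
        x = rng.normal(size=(2, c, hw, hw)).astype(np.float32)
        out = m(Tensor(x))
        ref = oracles.ref_gmsa(x, m)
        assert np.allclose(out.data, ref, atol=1e-5)

    def test_scale1_collapses_to_projected_global_mean(self, rng):
        m = GroupedMultiScaleAttention(GMSAConfig(4, [1]),
                                       np.random.default_rng(3))
        x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        out = m(Tensor(x))
        # single token -> attention is the identity on the value token
        flat = x.reshape(1, 4, 36).transpose(0, 2, 1)
        v = flat @ m.v_proj[0].weight.data + m.v_proj[0].bias.data
        token = v.mean(axis=1)                       # global-mean value token
        proj = token @ m.out_proj[0].weight.data + m.out_proj[0].bias.data
        expect = np.broadcast_to(proj[:, :, None, None], (1, 4, 6, 6))
        assert np.allclose(out.data, expect, atol=1e-6)

    def test_scale_exceeding_resolution_raises(self, rng):
        m = GroupedMultiScaleAttention(GMSAConfig(4, [8]),
                                       np.random.default_rng(0))
        with pytest.raises(ConfigurationError, match="8.*4x4"):
            m(Tensor(np.zeros((1, 4, 4, 4), dtype=np.float32)))


class TestCost:
    def test_single_group_s1(self):
        cost = gmsa_cost(GMSAConfig(16, [1]), 8)
        assert cost["groups"][0]["tokens"] == 1
        assert cost["groups"][0]["attention_mults"] == 16

    def test_scale_ratio_is_fourth_power(self):
        c2 = gmsa_cost(GMSAConfig(8, [2, 2]), 16)
        c4 = gmsa_cost(GMSAConfig(8, [4, 4]), 16)
        assert c4["total_attention_mults"] == 16 * c2["total_attention_mults"]

    def test_cost_shares_follow_s4(self):
        cost = gmsa_cost(GMSAConfig(16, [1, 2, 4, 7]), 56)
        shares = [g["attention_mults"] for g in cost["groups"]]
        assert shares == [4 * s ** 4 for s in (1, 2, 4, 7)]

    def test_measured_multiplies_scale_as_s4(self):
        """Log-log slope of counted attention-score multiplies vs s is 4."""
        rng = np.random.default_rng(0)
        counts = []
        for s in (2, 4, 8):
            m = GroupedMultiScaleAttention(GMSAConfig(8, [s]),
                                           np.random.default_rng(1))
            x = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
            with count_multiplies() as counter:
                m(x)
            counts.append(counter.count)
        slope = np.polyfit(np.log([2, 4, 8]), np.log(counts), 1)[0]
        assert abs(slope - 4.0) <= 0.01
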