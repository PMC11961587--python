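"""Decoder blocks (CPB, Inception, CSA, stems, fusion) and full wiring."""

import numpy as np
import pytest

from scaleformer.autodiff import Tensor
from scaleformer.decoder import (CSABlock, ContextPerceptionBlock,
                                 InceptionBlock, SimpleFusion, Stems)
from scaleformer.exceptions import ShapeError
from scaleformer.model import ScaleFormer, ScaleFormerConfig

import oracles


class TestCPB:
    def test_zero_fusion_conv_collapses_to_encoder_stream(self, rng):
        cpb = ContextPerceptionBlock(4, np.random.default_rng(0))
        cpb.fuse.weight.data[...] = 0.0
        cpb.fuse.bias.data[...] = 0.0
        enc = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        dec = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        assert np.array_equal(cpb(Tensor(enc), Tensor(dec)).data, enc)

    def test_spatial_mismatch_raises(self):
        cpb = ContextPerceptionBlock(4, np.random.default_rng(0))
        with pytest.raises(ShapeError):
            cpb(Tensor(np.zeros((1, 4, 4, 4), np.float32)),
                Tensor(np.zeros((1, 4, 8, 8), np.float32)))

    def test_matches_stepwise_oracle(self):
        rng = np.random.default_rng(3)
        cpb = ContextPerceptionBlock(2, np.random.default_rng(7))
        enc = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        dec = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        cat = np.concatenate([enc, dec], axis=1)
        fused = oracles.naive_conv2d(oracles.ref_se(cat.astype(np.float64),
                                                    cpb.se),
                                     cpb.fuse.weight.data,
                                     cpb.fuse.bias.data, padding=1)
        gate_logit = oracles.naive_conv2d(dec, cpb.gate_conv.weight.data,
                                          cpb.gate_conv.bias.data, padding=1)
        gate = 1.0 / (1.0 + np.exp(-gate_logit))
        expect = enc + gate * fused
        assert np.allclose(cpb(Tensor(enc), Tensor(dec)).data, expect,
                           atol=1e-5)


class TestInception:
    def test_shape_preserved(self, rng):
        blk = InceptionBlock(8, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 8, 5, 5)).astype(np.float32))
        assert blk(x).shape == (2, 8, 5, 5)

    def test_zero_weights_zero_output(self, rng):
        blk = InceptionBlock(8, np.random.default_rng(0))
        for p in blk.parameters():
            p.data[...] = 0.0
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        assert np.all(blk(x).data == 0.0)

    def test_projection_decomposes_over_branches(self, rng):
        """concat+1x1-projection equals the sum of per-branch projections."""
        blk = InceptionBlock(8, np.random.default_rng(1))
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        out = blk(x).data
        branches = blk.branches(x)
        w = blk.project.weight.data          # [8, 8, 1, 1]
        acc = np.zeros_like(out)
        for i, br in enumerate(branches):
            wi = w[:, i * 2:(i + 1) * 2]
            acc += np.einsum("bchw,oc->bohw", br.data, wi[:, :, 0, 0])
        acc += blk.project.bias.data[None, :, None, None]
        assert np.allclose(out, acc, atol=1e-5)


class TestCSA:
    def test_uniform_input_gives_spatially_constant_output(self):
        blk = CSABlock(4, np.random.default_rng(0))
        x = Tensor(np.full((1, 4, 6, 6), 0.7, dtype=np.float32))
        out = blk(x).data
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-6)

    def test_attention_multipliers_shrink_magnitude(self, rng):
        # both gates are sigmoids in (0,1): |out| < |in| elementwise
        blk = CSABlock(4, np.random.default_rng(1))
        x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        out = blk(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-6)
        assert np.all(np.sign(out) == np.sign(x))

    def test_matches_sequential_oracle(self):
        rng = np.random.default_rng(6)
        blk = CSABlock(2, np.random.default_rng(2))
        x = rng.normal(size=(1, 2, 3, 3)).astype(np.float32)
        h = oracles.ref_se(x.astype(np.float64), blk.channel_gate)
        stat = h.mean(axis=1, keepdims=True)
        stat = np.pad(stat, ((0, 0), (0, 0), (3, 3), (3, 3)), mode="edge")
        gate_logit = oracles.naive_conv2d(stat, blk.spatial_conv.weight.data,
                                          blk.spatial_conv.bias.data)
        expect = h / (1.0 + np.exp(-gate_logit))
        assert np.allclose(blk(Tensor(x)).data, expect, atol=1e-5)


class TestStemsAndFusion:
    def test_stem_resolutions(self, rng):
        stems = Stems(1, 4, np.random.default_rng(0))
        f_full, f_half = stems(Tensor(rng.normal(size=(1, 1, 16, 16))
                                      .astype(np.float32)))
        assert f_full.shape == (1, 4, 16, 16)
        assert f_half.shape == (1, 4, 8, 8)

    def test_half_features_computed_from_full_features(self, rng):
        stems = Stems(1, 4, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(1, 1, 8, 8)).astype(np.float32))
        f_full, f_half = stems(x)
        ref_half = stems.bn2(stems.conv2(f_full)).relu()
        assert np.allclose(f_half.data, ref_half.data, atol=1e-6)

    def test_fusion_shape_and_zero_collapse(self, rng):
        fuse = SimpleFusion(4, 2, 3, np.random.default_rng(0))
        high = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        low = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        out = fuse(high, low)
        assert out.shape == (1, 3, 8, 8)
        fuse.conv.weight.data[...] = 0.0
        fuse.conv.bias.data[...] = 0.0
        assert np.all(fuse(high, low).data == 0.0)

    def test_fusion_spatial_mismatch_raises(self, rng):
        fuse = SimpleFusion(4, 2, 3, np.random.default_rng(0))
        with pytest.raises(ShapeError):
            fuse(Tensor(np.zeros((1, 4, 4, 4), np.float32)),
                 Tensor(np.zeros((1, 2, 9, 9), np.float32)))


@pytest.fixture(scope="module")
def model224():
    cfg = ScaleFormerConfig(input_size=224, num_classes=9,
                            stage_channels=[8, 16, 32, 64],
                            stage_depths=[1, 1, 1, 1],
                            ffn_ratio=2, lpu_expand=2,
                            stem_channels=4)
    return ScaleFormer(cfg, np.random.default_rng(0))


class TestFullModelWiring:
    def test_224_input_9_classes_shapes(self, model224, rng):
        x = Tensor(rng.normal(size=(1, 1, 224, 224)).astype(np.float32))
        bundle = model224(x)
        assert bundle.main.shape == (1, 9, 224, 224)
        assert bundle.aux8.shape == (1, 9, 28, 28)
        assert bundle.aux16.shape == (1, 9, 14, 14)
        assert bundle.aux32.shape == (1, 9, 7, 7)
        for t in [bundle.main] + bundle.aux:
            assert np.all(np.isfinite(t.data))

    def test_aux_heads_isolated_from_main_branch(self, model224, rng):
        x = Tensor(rng.normal(size=(1, 1, 224, 224)).astype(np.float32))
        before = model224(x).main.data.copy()
        for head in (model224.decoder.aux_head8, model224.decoder.aux_head16,
                     model224.decoder.aux_head32):
            head.weight.data[...] = 0.0
            head.bias.data[...] = 0.0
        after = model224(x).main.data
        assert np.array_equal(before, after)
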