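"""Encoder branches, fusion plumbing and decoder: shape contracts, gradient
flow, branch swaps, and parameter-count sanity at full scale."""

import numpy as np
import pytest

from conftest import micro_model_config
from fundusseg.autograd import Tensor, no_grad
from fundusseg.decoder import Decoder, DecoderBlock, DecoderConfig, SkipMerge
from fundusseg.encoder import EncoderConfig, MultiBranchEncoder
from fundusseg.losses import combined_loss
from fundusseg.model import FundusTumorNet, ModelConfig
from fundusseg.pyramid import build_pyramid

RNG = np.random.default_rng(0)


def micro_encoder(**kwargs) -> MultiBranchEncoder:
    cfg = EncoderConfig(micro_scale=4, window_size=4, **kwargs)
    return MultiBranchEncoder(cfg, np.random.default_rng(0))


class TestEncoderShapes:
    def test_micro_branch_shapes(self):
        enc = micro_encoder()
        pyr = build_pyramid(RNG.random((1, 3, 64, 64), dtype=np.float32))
        with no_grad():
            feats = enc(pyr)
        assert feats.f1.shape == feats.f2.shape == feats.f3.shape == (1, 192, 2, 2)
        assert [m.shape for m in feats.stage_maps[4]] == [(1, 24, 16, 16)] * 2
        assert [m.shape for m in feats.stage_maps[8]] == [(1, 48, 8, 8)] * 3
        assert [m.shape for m in feats.stage_maps[16]] == [(1, 96, 4, 4)] * 3
        assert [m.shape for m in feats.stage_maps[32]] == [(1, 192, 2, 2)] * 3

    def test_mid_branch_stage1_preserves_resolution(self):
        enc = micro_encoder()
        with no_grad():
            maps = enc.enc2_forward(Tensor(RNG.random((1, 96, 16, 16), dtype=np.float32)))
        assert maps[0].shape == (1, 24, 16, 16)    # 1x1 stem: no downsampling
        assert maps[-1].shape == (1, 192, 2, 2)

    def test_small_branch_has_three_stages(self):
        enc = micro_encoder()
        with no_grad():
            maps = enc.enc3_forward(Tensor(RNG.random((1, 192, 8, 8), dtype=np.float32)))
        assert len(maps) == 3
        assert maps[0].shape == (1, 48, 8, 8)      # stage-2 stem preserves size
        assert maps[-1].shape == (1, 192, 2, 2)

    def test_determinism_in_eval_mode(self):
        enc = micro_encoder()
        x = RNG.random((1, 3, 64, 64), dtype=np.float32)
        with no_grad():
            a = enc(build_pyramid(x)).f1.data
            b = enc(build_pyramid(x)).f1.data
        assert np.array_equal(a, b)

    def test_zero_input_zero_bias_stem_gives_zero(self):
        enc = micro_encoder()
        stem = enc.enc2.stem
        stem.proj.bias.data[:] = 0.0
        stem.norm.bias.data[:] = 0.0
        with no_grad():
            out = stem(Tensor(np.zeros((1, 96, 8, 8), dtype=np.float32)))
        assert np.allclose(out.data, 0.0)


class TestEncoderVariants:
    def test_convnext_center_swap_builds(self):
        enc = micro_encoder(center_branch="convnext")
        pyr = build_pyramid(RNG.random((1, 3, 64, 64), dtype=np.float32))
        with no_grad():
            feats = enc(pyr)
        assert feats.f1.shape == feats.f2.shape == feats.f3.shape == (1, 192, 2, 2)

    @pytest.mark.parametrize("variant", ["swin_only", "convnext_only", "resnet_only"])
    def test_single_branch_variants(self, variant):
        model = FundusTumorNet(micro_model_config(variant=variant))
        out = model.predict(RNG.random((1, 3, 64, 64), dtype=np.float32))
        assert out["mask_prob"].shape == (1, 64, 64)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(center_branch="vgg")
        with pytest.raises(ValueError):
            EncoderConfig(variant="other")
        with pytest.raises(ValueError):
            EncoderConfig(stage_channels=(96, 96, 384, 768))


def test_full_scale_parameter_counts_match_tiny_variants():
    """Branch parameter totals stay within 15% of the published Tiny models
    (Swin-T 28.3M, ConvNeXt-T 28.6M) — a sanity check on faithful dimensioning."""
    enc = MultiBranchEncoder(EncoderConfig(), np.random.default_rng(0))
    assert abs(enc.enc1.num_parameters() - 28.3e6) / 28.3e6 < 0.15
    assert abs(enc.enc2.num_parameters() - 28.6e6) / 28.6e6 < 0.15
    assert abs(enc.enc3.num_parameters() - 28.6e6) / 28.6e6 < 0.15


def test_gradients_reach_all_three_branches(micro_model, tiny_dataset):
    X, y, labels = tiny_dataset
    out = micro_model(X[:2], class_override=labels[:2])
    bd = combined_loss(y[:2].astype(np.float32), out["mask_prob"], labels[:2],
                       out["class_probs"])
    micro_model.zero_grad()
    bd.total.backward()
    for branch in (micro_model.encoder.enc1, micro_model.encoder.enc2,
                   micro_model.encoder.enc3):
        norms = [np.linalg.norm(p.grad) for p in branch.parameters()
                 if p.grad is not None]
        assert norms and max(norms) > 0
    micro_model.zero_grad()


class TestDecoder:
    def test_block_shapes(self):
        rng = np.random.default_rng(0)
        blk = DecoderBlock(768, 384, 2, rng)
        with no_grad():
            out = blk(Tensor(rng.random((1, 768, 14, 14), dtype=np.float32)))
        assert out.shape == (1, 384, 28, 28)
        blk4 = DecoderBlock(96, 3, 4, rng)
        with no_grad():
            out4 = blk4(Tensor(rng.random((1, 96, 112, 112), dtype=np.float32)))
        assert out4.shape == (1, 3, 448, 448)
        with pytest.raises(ValueError):
            DecoderBlock(8, 4, 3, rng)

    def test_zero_weights_zero_output(self):
        rng = np.random.default_rng(1)
        blk = DecoderBlock(4, 2, 2, rng)
        for p in blk.parameters():
            p.data[:] = 0.0
        with no_grad():
            out = blk(Tensor(rng.random((1, 4, 3, 3), dtype=np.float32)))
        assert np.allclose(out.data, 0.0)

    def test_skip_merge_zero_projection_is_identity(self):
        rng = np.random.default_rng(2)
        merge = SkipMerge(6, 4, rng)
        merge.proj.weight.data[:] = 0.0
        merge.proj.bias.data[:] = 0.0
        dec_map = rng.random((1, 4, 5, 5), dtype=np.float32)
        skips = [Tensor(rng.random((1, 3, 5, 5), dtype=np.float32)) for _ in range(2)]
        with no_grad():
            out = merge(Tensor(dec_map), skips)
        assert np.allclose(out.data, dec_map)

    def test_skip_merge_rejects_resolution_mismatch(self):
        rng = np.random.default_rng(3)
        merge = SkipMerge(3, 4, rng)
        with pytest.raises(ValueError, match="resolution"):
            merge(Tensor(np.zeros((1, 4, 5, 5))), [Tensor(np.zeros((1, 3, 4, 4)))])

    def test_decode_shape_chain_micro(self, micro_model, tiny_dataset):
        X, _, labels = tiny_dataset
        out = micro_model.predict(X[:1])
        assert out["mask_prob"].shape == (1, 64, 64)

    def test_zeroing_skips_changes_output(self, tiny_dataset):
        X, _, _ = tiny_dataset
        model = FundusTumorNet(micro_model_config(seed=5))
        base = model.predict(X[:1])["mask_prob"]
        for skip in model.decoder.skips:
            skip.proj.weight.data[:] = 0.0
            skip.proj.bias.data[:] = 0.0
        altered = model.predict(X[:1])["mask_prob"]
        assert np.abs(base - altered).max() > 0

    def test_channel_sequence_must_end_in_three(self):
        with pytest.raises(ValueError):
            DecoderConfig(channel_sequence=(384, 192, 96, 4))
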