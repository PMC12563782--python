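"""CBAM attention blocks and the U-shaped segmenter."""

import numpy as np
import pytest

from finseg import nn
from finseg.cbam_unet import (
    CBAM,
    ChannelAttention,
    SpatialAttention,
    UNet,
    UNetConfig,
    build_unet,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
)
from finseg.nn.tensor import Tensor


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        ca = ChannelAttention(8, reduction=4)
        ca.fc1.weight.data[:] = 0
        ca.fc2.weight.data[:] = 0
        out = ca(Tensor(rng.random((2, 8, 4, 4)).astype(np.float32)))
        assert out.shape == (2, 8, 1, 1)
        assert np.allclose(out.data, 0.5)

    def test_constant_channels_match_direct_formula(self, rng):
        """With per-channel constant input, avg-pool equals max-pool, so
        the gate is logistic(2 * MLP(d)); check against a direct numpy
        evaluation of the shared perceptron."""
        ca = ChannelAttention(4, reduction=2)
        d = np.array([1.0, -2.0, 0.5, 3.0], np.float32)
        x = np.broadcast_to(d[None, :, None, None], (1, 4, 3, 3)).copy()
        out = ca(Tensor(x)).data.reshape(-1)
        w1, w2 = ca.fc1.weight.data, ca.fc2.weight.data
        mlp = np.maximum(d @ w1, 0) @ w2
        assert out == pytest.approx(_sigmoid(2 * mlp), abs=1e-6)

    def test_channel_permutation_equivariance(self, rng):
        ca = ChannelAttention(6, reduction=2)
        x = rng.random((1, 6, 5, 5)).astype(np.float32)
        perm = rng.permutation(6)
        base = ca(Tensor(x)).data.reshape(-1)
        ca.fc1.weight.data = ca.fc1.weight.data[perm]
        ca.fc2.weight.data = ca.fc2.weight.data[:, perm]
        permuted = ca(Tensor(x[:, perm])).data.reshape(-1)
        assert permuted == pytest.approx(base[perm], abs=1e-6)

    def test_oracle_direct_summation(self, rng):
        """Agree with a slow loop-based oracle on random small tensors."""
        for _ in range(20):
            c = int(rng.integers(2, 8))
            ca = ChannelAttention(c, reduction=2)
            x = rng.standard_normal((1, c, 4, 4)).astype(np.float32)
            got = ca(Tensor(x)).data.reshape(-1)
            avg = np.array([x[0, i].mean() for i in range(c)], np.float32)
            mx = np.array([x[0, i].max() for i in range(c)], np.float32)
            w1, w2 = ca.fc1.weight.data, ca.fc2.weight.data
            ref = _sigmoid(np.maximum(avg @ w1, 0) @ w2
                           + np.maximum(mx @ w1, 0) @ w2)
            assert got == pytest.approx(ref, abs=1e-5)


class TestSpatialAttention:
    def test_zero_filter_uniform_half(self, rng):
        sa = SpatialAttention(7)
        sa.conv.weight.data[:] = 0
        out = sa(Tensor(rng.random((2, 5, 6, 6)).astype(np.float32)))
        assert out.shape == (2, 1, 6, 6)
        assert np.allclose(out.data, 0.5)

    def test_output_shape_any_channel_count(self, rng):
        sa = SpatialAttention(7)
        for c in (1, 3, 16):
            out = sa(Tensor(rng.random((1, c, 8, 8)).astype(np.float32)))
            assert out.shape == (1, 1, 8, 8)

    def test_horizontal_flip_with_symmetric_filter(self, rng):
        sa = SpatialAttention(7)
        w = sa.conv.weight.data
        sa.conv.weight.data = (w + w[:, :, :, ::-1]) / 2  # symmetrize
        x = rng.random((1, 4, 8, 8)).astype(np.float32)
        out = sa(Tensor(x)).data
        flipped = sa(Tensor(x[..., ::-1].copy())).data
        assert flipped == pytest.approx(out[..., ::-1], abs=1e-6)

    def test_oracle_direct_summation(self, rng):
        for _ in range(20):
            c = int(rng.integers(1, 5))
            sa = SpatialAttention(3)
            x = rng.standard_normal((1, c, 6, 6)).astype(np.float32)
            got = sa(Tensor(x)).data[0, 0]
            stacked = np.stack([x[0].mean(axis=0), x[0].max(axis=0)])
            pad = np.pad(stacked, ((0, 0), (1, 1), (1, 1)))
            w = sa.conv.weight.data[0]
            ref = np.zeros((6, 6))
            for i in range(6):
                for j in range(6):
                    ref[i, j] = (pad[:, i:i + 3, j:j + 3] * w).sum()
            assert got == pytest.approx(_sigmoid(ref), abs=1e-5)


class TestCBAM:
    def test_zero_weight_quarter_scaling(self, rng):
        cb = CBAM(4, reduction=2)
        cb.channel.fc1.weight.data[:] = 0
        cb.channel.fc2.weight.data[:] = 0
        cb.spatial.conv.weight.data[:] = 0
        x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
        out = cb(Tensor(x)).data
        assert out == pytest.approx(0.25 * x, abs=1e-6)

    def test_contraction_and_shape(self, rng):
        cb = CBAM(8)
        x = rng.standard_normal((2, 8, 6, 6)).astype(np.float32)
        out = cb(Tensor(x)).data
        assert out.shape == x.shape
        assert (np.abs(out) <= np.abs(x) + 1e-7).all()


class TestUNetStructure:
    def test_default_config_bottleneck_1024(self):
        cfg = UNetConfig()
        assert cfg.base_width == 64 and cfg.depth == 4
        assert cfg.bottleneck_channels == 1024

    def test_channel_ladder_and_output_shape(self, rng):
        cfg = UNetConfig(base_width=4, depth=3, n_classes=4, use_cbam=True)
        model = build_unet(cfg, seed=0)
        x = Tensor(rng.random((1, 3, 32, 32)).astype(np.float32))
        skips = []
        t = x
        for i, (blk, att) in enumerate(zip(model.enc, model.enc_cbam)):
            t = att(blk(t))
            assert t.shape == (1, 4 * 2 ** i, 32 // 2 ** i, 32 // 2 ** i)
            skips.append(t)
            t = model.pool(t)
        t = model.bottleneck(t)
        assert t.shape == (1, 32, 4, 4)
        out = model(x)
        assert out.shape == (1, 4, 32, 32)

    def test_bottleneck_spatial_size_512_depth4(self):
        # 512 / 2^4 = 32 per side; verified structurally via a forward
        # hook-free walk at reduced width to keep it fast
        cfg = UNetConfig(base_width=1, depth=4, n_classes=2, batch_norm=False)
        model = build_unet(cfg, seed=0)
        x = Tensor(np.zeros((1, 3, 512, 512), np.float32))
        t = x
        for blk in model.enc:
            t = model.pool(blk(t))
        t = model.bottleneck(t)
        assert t.shape[-2:] == (32, 32)

    def test_smoke_tiny_forward(self, rng):
        cfg = UNetConfig(base_width=1, depth=1, n_classes=2, batch_norm=False)
        model = build_unet(cfg, seed=0)
        out = model(Tensor(rng.random((1, 3, 8, 8)).astype(np.float32)))
        assert out.shape == (1, 2, 8, 8)
        assert np.isfinite(out.data).all()

    def test_indivisible_input_rejected(self):
        model = build_unet(UNetConfig(base_width=2, depth=3, n_classes=2), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model(Tensor(np.zeros((1, 3, 36, 36), np.float32)))


class TestPredict:
    def test_probabilities_form_simplex(self, rng, sample_160):
        cfg = UNetConfig(base_width=2, depth=2, n_classes=4)
        model = build_unet(cfg, seed=0)
        mask, probs = predict_mask(model, sample_160.image)
        assert mask.shape == sample_160.part_mask.shape
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_zeroed_head_uniform_argmax_class0(self, sample_160):
        cfg = UNetConfig(base_width=2, depth=2, n_classes=3)
        model = build_unet(cfg, seed=0)
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        mask, probs = predict_mask(model, sample_160.image)
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-6)
        assert (mask == 0).all()

    def test_checkpoint_round_trip(self, tmp_path, rng, sample_160):
        cfg = UNetConfig(base_width=2, depth=2, n_classes=4, use_cbam=True)
        model = build_unet(cfg, seed=3)
        path = tmp_path / "seg.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        m1, p1 = predict_mask(model, sample_160.image)
        m2, p2 = predict_mask(clone, sample_160.image)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_allclose(p1, p2, atol=1e-6)


class TestTraining:
    def test_one_epoch_smoke_and_reproducibility(self, dataset_160):
        from finseg.cbam_unet import SegTrainConfig, train_segmenter
        from finseg.preprocess import resize_bicubic

        data = [(resize_bicubic(s.image, (32, 32)),
                 np.asarray(
                     __import__("PIL.Image", fromlist=["Image"]).fromarray(
                         s.part_mask).resize((32, 32), 0))
                 ) for s in dataset_160[:4]]
        cfg = UNetConfig(base_width=2, depth=2, n_classes=4)
        tcfg = SegTrainConfig(epochs=1, batch_size=4, seed=0)
        m1, h1 = train_segmenter(build_unet(cfg, seed=1), data, tcfg)
        assert len(h1) == 1 and np.isfinite(h1[0]["train_loss"])
        m2, h2 = train_segmenter(build_unet(cfg, seed=1), data, tcfg)
        assert h1[0]["train_loss"] == pytest.approx(h2[0]["train_loss"], rel=1e-6)

    def test_bad_mask_labels_rejected(self, dataset_160):
        from finseg.cbam_unet import SegTrainConfig, train_segmenter

        s = dataset_160[0]
        bad = s.part_mask.copy()
        bad[0, 0] = 7
        with pytest.raises(ValueError, match="n_classes"):
            train_segmenter(build_unet(UNetConfig(base_width=2, depth=2), seed=0),
                            [(s.image, bad)], SegTrainConfig(epochs=1))
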