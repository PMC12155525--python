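"""SegNet building blocks: convolution oracle, gradients, attention, training."""

import numpy as np
import pytest
from scipy import signal

import dentalseg.nn.layers as nnl
from dentalseg.nn import (
    ChannelAttention,
    ImagePair,
    SegNetConfig,
    SpatialAttention,
    TrainConfig,
    build_segnet,
    load_segnet,
    predict,
    save_segnet,
    softmax,
    softmax_cross_entropy,
    split_by_scan,
    train,
)
from dentalseg.nn.layers import Conv2d, ConvTranspose2d


class TestConvOracle:
    def test_conv2d_matches_scipy_correlate(self):
        """Independent oracle: same-padded correlation per channel pair."""
        rng = np.random.default_rng(0)
        conv = Conv2d(3, 4, rng=rng)
        x = rng.random((1, 3, 9, 9)).astype(np.float32)
        out = conv.forward(x)
        for o in range(4):
            expected = sum(
                signal.correlate2d(x[0, c], conv.W[o, c], mode="same")
                for c in range(3)
            ) + conv.b[o]
            np.testing.assert_allclose(out[0, o], expected, atol=1e-4)

    def test_transposed_conv_is_adjoint_of_downsampling_conv(self):
        """<y, up(x)> == <down(y), x> for matching kernels."""
        rng = np.random.default_rng(1)
        up = ConvTranspose2d(3, 2, rng=rng)
        x = rng.random((1, 3, 5, 5)).astype(np.float32)
        y = rng.random((1, 2, 10, 10)).astype(np.float32)
        lhs = float((up.forward(x) - up.b[None, :, None, None]).ravel() @ y.ravel())
        # adjoint: strided 2x2 correlation of y with the same kernels
        rhs = 0.0
        for ci in range(3):
            for co in range(2):
                acc = signal.correlate2d(y[0, co], up.W[ci, co], mode="valid")[::2, ::2]
                rhs += float((acc * x[0, ci]).sum())
        assert lhs == pytest.approx(rhs, rel=1e-4)


class TestGradients:
    @pytest.mark.parametrize("placement", ["none", "end", "center"])
    def test_finite_difference_gradients(self, placement):
        old = nnl.DTYPE
        nnl.DTYPE = np.float64
        try:
            cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=8,
                               base_channels=4, attention_placement=placement)
            model = build_segnet(cfg, seed=0)
            rng = np.random.default_rng(1)
            x = rng.random((2, 3, 8, 8))
            y = rng.integers(0, 4, (2, 8, 8))
            loss, grad = softmax_cross_entropy(model.forward(x, train=True), y)
            model.backward(grad)
            params = model.params()
            gmax = max(np.abs(g).max() for _, g in params)
            checked = 0
            rng2 = np.random.default_rng(2)
            for p, g in params:
                idx = tuple(rng2.integers(0, s) for s in p.shape)
                if abs(g[idx]) < 1e-3 * gmax:
                    continue  # zero/negligible gradients drown in fd noise
                eps = 1e-6
                orig = p[idx]
                p[idx] = orig + eps
                lp = softmax_cross_entropy(model.forward(x, train=True), y)[0]
                p[idx] = orig - eps
                lm = softmax_cross_entropy(model.forward(x, train=True), y)[0]
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-9)
                checked += 1
            assert checked >= 5
        finally:
            nnl.DTYPE = old


class TestAttention:
    def test_channel_gate_forced_open_is_identity(self):
        att = ChannelAttention(8)
        att.b2[:] = 50.0  # sigmoid saturates at 1
        x = np.random.default_rng(0).random((1, 8, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(att.forward(x), x, atol=1e-6)

    def test_spatial_gate_forced_open_is_identity(self):
        att = SpatialAttention()
        att.conv.W[:] = 0.0
        att.conv.b[:] = 50.0
        x = np.random.default_rng(0).random((1, 8, 6, 6)).astype(np.float32)
        np.testing.assert_allclose(att.forward(x), x, atol=1e-6)

    @pytest.mark.parametrize("att", [ChannelAttention(8), SpatialAttention()])
    def test_zero_input_gives_zero_output_and_preserves_shape(self, att):
        x = np.zeros((2, 8, 6, 6), dtype=np.float32)
        out = att.forward(x)
        assert out.shape == x.shape
        np.testing.assert_array_equal(out, 0.0)

    def test_spatial_weights_scale_rows_proportionally(self):
        """On a spatially constant input, output ratios equal gate ratios."""
        att = SpatialAttention()
        x = np.ones((1, 4, 8, 8), dtype=np.float32)
        out = att.forward(x)
        g = att._g[0, 0]
        np.testing.assert_allclose(out[0, 0], g, atol=1e-6)
        np.testing.assert_allclose(out[0, 3], g, atol=1e-6)


class TestModelStructure:
    def test_softmax_normalises_per_pixel(self):
        cfg = SegNetConfig(encoder_layers=3, n_classes=6, input_size=16, base_channels=4)
        model = build_segnet(cfg, seed=1)
        x = np.random.default_rng(0).random((1, 3, 16, 16)).astype(np.float32)
        p = softmax(model.forward(x, train=False))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)
        assert p.shape == (1, 6, 16, 16)

    def test_placements_differ_in_parameters_not_classes(self):
        cfgs = {
            pl: build_segnet(
                SegNetConfig(encoder_layers=2, n_classes=5, input_size=16,
                             base_channels=4, attention_placement=pl), seed=0)
            for pl in ("none", "end", "center")
        }
        assert cfgs["end"].n_parameters != cfgs["center"].n_parameters
        assert cfgs["none"].n_parameters < cfgs["end"].n_parameters
        for m in cfgs.values():
            assert m.head.W.shape[0] == 5

    def test_attention_none_is_strict_subgraph(self):
        """The plain model's parameter list is a prefix-compatible subset:
        same shapes in the same order once attention params are removed."""
        plain = build_segnet(SegNetConfig(encoder_layers=2, n_classes=5,
                                          input_size=16, base_channels=4), seed=0)
        end = build_segnet(SegNetConfig(encoder_layers=2, n_classes=5, input_size=16,
                                        base_channels=4, attention_placement="end"),
                           seed=0)
        att_params = sum(len(a.params()) for a in end.end_attention)
        shapes_plain = [p.shape for p, _ in plain.params()]
        shapes_end = [p.shape for p, _ in end.params()]
        del shapes_end[-(att_params + 2):-2]  # drop attention (head is last 2)
        assert shapes_plain == shapes_end

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_segnet(SegNetConfig(encoder_layers=4, input_size=100))

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=16, base_channels=4)
        model = build_segnet(cfg, seed=3)
        save_segnet(model, tmp_path / "m.npz")
        back = load_segnet(tmp_path / "m.npz")
        assert back.config == cfg
        x = np.random.default_rng(0).random((1, 3, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x, False), back.forward(x, False))


class TestTraining:
    def _pair(self, seed=0, size=16, classes=4):
        rng = np.random.default_rng(seed)
        img = rng.random((3, size, size)).astype(np.float32)
        lab = rng.integers(0, classes, (size, size))
        return ImagePair(img, lab, scan_id=seed)

    def test_zero_epochs_leaves_weights_untouched(self):
        cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=16, base_channels=4)
        model = build_segnet(cfg, seed=0)
        before = model.get_weights()
        train(model, [self._pair()], TrainConfig(epochs=0))
        for b, a in zip(before, model.get_weights()):
            np.testing.assert_array_equal(b, a)

    def test_fixed_seed_reproduces_history(self):
        cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=16, base_channels=4)
        hists = []
        for _ in range(2):
            model = build_segnet(cfg, seed=0)
            _, h = train(model, [self._pair(1), self._pair(2)],
                         TrainConfig(epochs=3, learning_rate=1e-3, seed=5))
            hists.append(h["train_loss"])
        assert hists[0] == hists[1]

    def test_loss_decreases_on_small_set(self):
        cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=16, base_channels=4)
        model = build_segnet(cfg, seed=0)
        pairs = [self._pair(s) for s in range(4)]
        _, h = train(model, pairs, TrainConfig(epochs=20, learning_rate=1e-3, seed=0))
        assert h["train_loss"][-1] < h["train_loss"][0]

    def test_split_by_scan_is_disjoint(self):
        pairs = [self._pair(seed=s) for s in range(10) for _ in range(3)]
        tr, va, te = split_by_scan(pairs, seed=1)
        scans = [{p.scan_id for p in s} for s in (tr, va, te)]
        assert not (scans[0] & scans[1] or scans[0] & scans[2] or scans[1] & scans[2])
        assert sum(len(s) for s in (tr, va, te)) == 30

    def test_scan_in_two_splits_is_an_error(self):
        cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=16, base_channels=4)
        model = build_segnet(cfg, seed=0)
        shared = self._pair(seed=7)
        with pytest.raises(ValueError, match="two splits"):
            train(model, [shared], TrainConfig(epochs=1), val_set=[shared])

    def test_predict_is_deterministic_and_palette_shaped(self):
        cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=16, base_channels=4)
        model = build_segnet(cfg, seed=0)
        img = self._pair().image
        a, b = predict(model, img), predict(model, img)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (16, 16)
        assert set(np.unique(a)) <= set(range(4))

    def test_predict_rejects_wrong_size(self):
        cfg = SegNetConfig(encoder_layers=2, n_classes=4, input_size=16, base_channels=4)
        model = build_segnet(cfg, seed=0)
        with pytest.raises(ValueError, match="16x16"):
            predict(model, np.zeros((3, 8, 8), np.float32))
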