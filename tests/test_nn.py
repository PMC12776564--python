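"""Network contracts: shapes, parameter sharing, gradients, backends."""

import numpy as np
import pytest

import eitsep.nn.layers as nnl
from eitsep.losses import bce, bce_grad_logits, sigmoid
from eitsep.models import ClassicalUNet, SemiSiameseUNet
from eitsep.nn.layers import Conv3x3
from eitsep.nn.unet import (BaselineNet, SemiSiameseNet, get_weights,
                            parameter_count, set_training, set_weights)


class TestShapes:
    @pytest.mark.parametrize("depth,base", [(3, 8), (4, 8), (3, 16), (4, 32)])
    def test_output_shapes_and_range(self, depth, base):
        net = SemiSiameseNet(base, depth, np.random.default_rng(0))
        x = np.random.default_rng(1).random((2, 1, 32, 32)).astype(np.float32)
        ll, hl = net.forward(x)
        assert ll.shape == hl.shape == (2, 1, 32, 32)
        for p in (sigmoid(ll), sigmoid(hl)):
            assert np.all((p > 0) & (p < 1))

    def test_bottleneck_resolution_from_depth(self):
        net = SemiSiameseNet(8, 4, np.random.default_rng(0))
        x = np.random.default_rng(1).random((1, 1, 32, 32)).astype(np.float32)
        feat, skips = net.encoder.forward(x)
        assert feat.shape[-2:] == (4, 4)  # three 2x downsamplings
        assert [s.shape[-1] for s in skips] == [32, 16, 8]

    def test_baseline_two_channel_head(self):
        net = BaselineNet(8, 3, np.random.default_rng(0))
        x = np.random.default_rng(1).random((3, 1, 32, 32)).astype(np.float32)
        ll, hl = net.forward(x)
        assert ll.shape == hl.shape == (3, 1, 32, 32)


class TestParameterStructure:
    def test_decoders_have_identical_topology(self):
        net = SemiSiameseNet(8, 3, np.random.default_rng(0))
        shapes_l = [p.value.shape for p in net.decoder_lung.parameters()]
        shapes_h = [p.value.shape for p in net.decoder_heart.parameters()]
        assert shapes_l == shapes_h

    def test_encoder_matches_baseline_encoder(self):
        semi = SemiSiameseNet(8, 3, np.random.default_rng(0))
        base = BaselineNet(8, 3, np.random.default_rng(0))
        n_semi = sum(p.value.size for p in semi.encoder.parameters())
        n_base = sum(p.value.size for p in base.encoder.parameters())
        assert n_semi == n_base

    def test_baseline_smaller_than_semi_siamese(self):
        semi = SemiSiameseNet(8, 3, np.random.default_rng(0))
        base = BaselineNet(8, 3, np.random.default_rng(0))
        assert parameter_count(base) < parameter_count(semi)

    def test_weight_snapshot_roundtrip(self):
        net = SemiSiameseNet(4, 3, np.random.default_rng(0))
        w = get_weights(net)
        for p in net.parameters():
            p.value += 1.0
        set_weights(net, w)
        for p, orig in zip(net.parameters(), w):
            assert np.array_equal(p.value, orig)


class TestSharingContracts:
    def _nets_and_input(self):
        net = SemiSiameseNet(4, 3, np.random.default_rng(0))
        set_training(net, False)
        x = np.random.default_rng(2).random((2, 1, 32, 32)).astype(np.float32)
        return net, x

    def test_encoder_perturbation_changes_both_heads(self):
        net, x = self._nets_and_input()
        ll0, hl0 = net.forward(x)
        net.encoder.blocks[0].layers[0].w.value[0, 0] += 0.5
        ll1, hl1 = net.forward(x)
        assert not np.array_equal(ll0, ll1)
        assert not np.array_equal(hl0, hl1)

    def test_lung_decoder_perturbation_leaves_heart_bitwise_identical(self):
        net, x = self._nets_and_input()
        _, hl0 = net.forward(x)
        net.decoder_lung.head.w.value += 1.0
        net.decoder_lung.blocks[0].layers[0].w.value += 0.3
        _, hl1 = net.forward(x)
        assert np.array_equal(hl0, hl1)

    def test_deterministic_inference(self):
        net, x = self._nets_and_input()
        out1 = net.forward(x)
        out2 = net.forward(x)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])

    def test_heart_loss_reaches_shared_encoder(self):
        net, x = self._nets_and_input()
        set_training(net, True)
        _, hl = net.forward(x)
        t = np.zeros_like(hl)
        for p in net.parameters():
            p.grad[...] = 0
        net.backward(np.zeros_like(hl), bce_grad_logits(sigmoid(hl), t))
        enc_norm = sum(float(np.abs(p.grad).sum())
                       for p in net.encoder.parameters())
        assert enc_norm > 0
        # and the lung decoder receives nothing from the heart loss
        lung_norm = sum(float(np.abs(p.grad).sum())
                        for p in net.decoder_lung.parameters())
        assert lung_norm == 0


class TestGradients:
    def test_backprop_matches_finite_differences(self, monkeypatch):
        """Full-graph gradient check in float64 against central differences."""
        monkeypatch.setattr(nnl, "DTYPE", np.float64)
        rng = np.random.default_rng(0)
        net = SemiSiameseNet(2, 3, rng)
        for p in net.parameters():
            p.value = p.value.astype(np.float64)
            if p.value.ndim == 1:   # move biases off the ReLU kinks
                p.value = p.value + rng.normal(0, 0.05, p.value.shape)
            p.grad = np.zeros_like(p.value)
        x = rng.random((4, 1, 8, 8))
        tl = (rng.random((4, 1, 8, 8)) > 0.5).astype(float)
        th = (rng.random((4, 1, 8, 8)) > 0.5).astype(float)

        def loss():
            ll, hl = net.forward(x)
            return bce(sigmoid(ll), tl) + 2.0 * bce(sigmoid(hl), th)

        ll, hl = net.forward(x)
        for p in net.parameters():
            p.grad[...] = 0
        net.backward(bce_grad_logits(sigmoid(ll), tl),
                     2.0 * bce_grad_logits(sigmoid(hl), th))
        check_rng = np.random.default_rng(9)
        for p in net.parameters():
            flat = p.value.ravel()
            for _ in range(2):
                j = check_rng.integers(flat.size)
                old, h = flat[j], 1e-5
                flat[j] = old + h
                lp = loss()
                flat[j] = old - h
                lm = loss()
                flat[j] = old
                num = (lp - lm) / (2 * h)
                ana = p.grad.ravel()[j]
                assert num == pytest.approx(ana, rel=5e-3, abs=1e-7)

    def test_conv_backends_agree(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 5, 16, 16)).astype(np.float32)
        a = Conv3x3(5, 7, np.random.default_rng(1), backend="numpy")
        b = Conv3x3(5, 7, np.random.default_rng(1), backend="numba")
        ya, yb = a.forward(x), b.forward(x)
        assert np.allclose(ya, yb, atol=1e-5)
        dy = rng.random(ya.shape).astype(np.float32)
        dxa, dxb = a.backward(dy), b.backward(dy)
        assert np.allclose(dxa, dxb, atol=1e-4)
        assert np.allclose(a.w.grad, b.w.grad, atol=1e-2)
        assert np.allclose(a.b.grad, b.b.grad, atol=1e-2)


class TestEstimators:
    def test_sklearn_params_roundtrip(self):
        m = SemiSiameseUNet(w_heart=1.8, epochs=3)
        params = m.get_params()
        assert params["w_heart"] == 1.8
        m2 = SemiSiameseUNet(**params)
        assert m2.get_params() == params
        m2.set_params(w_heart=2.0)
        assert m2.wc == 2.0

    def test_head_preactivation_zero_gives_half_output(self):
        m = SemiSiameseUNet(base_channels=4, depth=3, head_bias=0.0).build()
        for dec in (m.net_.decoder_lung, m.net_.decoder_heart):
            dec.head.w.value[...] = 0.0
            dec.head.b.value[...] = 0.0
        set_training(m.net_, False)
        proba = m.predict_proba(
            np.random.default_rng(0).random((2, 32, 32)).astype(np.float32))
        assert np.allclose(proba, 0.5)

    def test_overfits_single_sample(self, tiny_samples):
        from eitsep.data import samples_to_arrays
        X, y = samples_to_arrays(tiny_samples[:1])
        m = SemiSiameseUNet(base_channels=8, depth=3, epochs=600,
                            learning_rate=5e-3, batch_size=1,
                            augment_flip=False, random_state=0)
        m.fit(X, y)
        assert min(m.history_["train_loss"]) < 0.01

    def test_invalid_depth_for_grid_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            SemiSiameseUNet(depth=7).build()

    def test_baseline_estimator_output_channels(self):
        m = ClassicalUNet(base_channels=4, depth=3).build()
        set_training(m.net_, False)
        proba = m.predict_proba(
            np.random.default_rng(0).random((2, 32, 32)).astype(np.float32))
        assert proba.shape == (2, 2, 32, 32)
        assert np.all((proba > 0) & (proba < 1))
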