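import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import echoseg.network as net
from echoseg.network import (
    SELU_ALPHA,
    SELU_LAMBDA,
    NetworkSpec,
    alpha_dropout,
    build_model,
    load_checkpoint,
    padded_shape,
    predict,
    save_checkpoint,
    selu,
)
from echoseg.training import soft_dice_loss, soft_dice_loss_grad


class TestSelu:
    def test_zero(self):
        assert selu(0.0) == 0.0

    def test_one_is_lambda(self):
        assert selu(1.0) == pytest.approx(1.0507, abs=1e-12)

    def test_minus_one(self):
        # lambda * alpha * (exp(-1) - 1) with the printed constants
        assert selu(-1.0) == pytest.approx(-1.1113541067739783, rel=1e-12)

    def test_deep_negative_saturates(self):
        assert selu(-50.0) == pytest.approx(-SELU_LAMBDA * SELU_ALPHA, abs=1e-6)
        assert float(selu(-50.0)) == pytest.approx(-1.7581, abs=5e-5)

    def test_elementwise_on_grids(self):
        x = np.array([[0.0, 1.0], [-1.0, 2.0]])
        out = selu(x)
        assert out.shape == x.shape
        assert out[0, 1] == pytest.approx(1.0507)

    @given(st.floats(-100, 100, allow_nan=False))
    def test_bounded_below(self, x):
        assert selu(x) > -SELU_LAMBDA * SELU_ALPHA - 1e-12

    def test_monotone_and_continuous(self, rng):
        x = np.sort(rng.uniform(-20, 20, 100_000))
        y = selu(x)
        assert np.all(np.diff(y) >= 0)
        eps = 1e-9
        assert abs(selu(eps) - selu(-eps)) < 1e-6


class TestAlphaDropout:
    def test_inference_identity(self, rng):
        x = rng.normal(size=(100,))
        assert np.array_equal(alpha_dropout(x, 0.5, training=False, seed=0), x)

    def test_rate_zero_identity(self, rng):
        x = rng.normal(size=(100,))
        assert np.array_equal(alpha_dropout(x, 0.0, training=True, seed=0), x)

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            alpha_dropout(np.zeros(4), 1.0)

    def test_mean_variance_preserved(self, rng):
        x = rng.standard_normal(1_000_000)
        out = alpha_dropout(x, 0.5, training=True, seed=3)
        assert -0.02 <= out.mean() <= 0.02
        assert 0.95 <= out.var() <= 1.05

    def test_deterministic_per_seed(self, rng):
        x = rng.normal(size=(1000,))
        a = alpha_dropout(x, 0.3, training=True, seed=9)
        b = alpha_dropout(x, 0.3, training=True, seed=9)
        assert np.array_equal(a, b)

    def test_dropped_units_at_saturation(self, rng):
        x = rng.normal(size=(10000,))
        out = alpha_dropout(x, 0.5, training=True, seed=1)
        # dropped units all map to the same affine image of -lambda*alpha
        uniq, counts = np.unique(np.round(out, 12), return_counts=True)
        assert counts.max() > 4000  # ~half the units share one value


class TestBuildModel:
    def test_first_conv_param_count(self):
        model = build_model(NetworkSpec(variant="sunet", depth=1, channels=64), seed=0)
        conv = model.enc_blocks[0][0].conv
        assert conv.W.size + conv.b.size == 2 * 2 * 1 * 64 + 64 == 320

    def test_sunet_has_no_normalization_params(self):
        model = build_model(NetworkSpec(variant="sunet", depth=2, channels=8), seed=0)
        assert model.n_normalization_params() == 0

    def test_unet_has_normalization_params(self):
        model = build_model(NetworkSpec(variant="unet", depth=2, channels=8), seed=0)
        assert model.n_normalization_params() > 0

    def test_seeded_init_reproducible(self):
        spec = NetworkSpec(variant="sunet", depth=2, channels=4)
        a, b = build_model(spec, seed=5), build_model(spec, seed=5)
        for (na, pa, _, _), (nb, pb, _, _) in zip(a.params(), b.params()):
            assert na == nb
            assert np.array_equal(pa, pb)

    def test_in_shape_too_small_rejected(self):
        with pytest.raises(ValueError, match="2\\^depth"):
            build_model(NetworkSpec(variant="sunet", depth=4, channels=4, in_shape=(8, 8)), seed=0)

    def test_unet_dc_final_block_dilated(self):
        model = build_model(NetworkSpec(variant="unet_dc", depth=2, channels=4), seed=0)
        assert all(u.conv.dilation == 2 for u in model.dec_blocks[-1])
        assert all(u.conv.dilation == 1 for u in model.dec_blocks[0])

    def test_channel_defaults_per_variant(self):
        assert NetworkSpec().channels == 64
        assert NetworkSpec(variant="unet").channels == 64
        assert NetworkSpec(variant="unet_dc").channels == 128

    def test_last_block_has_extra_conv(self):
        model = build_model(NetworkSpec(variant="sunet", depth=2, channels=4), seed=0)
        assert len(model.dec_blocks[-1]) == 3
        assert len(model.dec_blocks[0]) == 2


class TestPredict:
    def test_output_shape_and_range(self, rng):
        model = build_model(NetworkSpec(variant="sunet", depth=2, channels=4), seed=0)
        x = rng.random((2, 21, 26)).astype(np.float32)
        p = predict(model, x)
        assert p.shape == x.shape
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_internal_padding_shape(self):
        assert padded_shape((107, 131), 3) == (112, 136)
        assert padded_shape((112, 136), 3) == (112, 136)

    def test_duplicated_image_identical_maps(self, rng):
        model = build_model(NetworkSpec(variant="sunet", depth=2, channels=4), seed=0)
        img = rng.random((20, 24)).astype(np.float32)
        p = predict(model, np.stack([img, img]))
        assert np.array_equal(p[0], p[1])

    def test_batch_composition_invariance_sunet(self, rng):
        model = build_model(NetworkSpec(variant="sunet", depth=2, channels=4), seed=0)
        a = rng.random((20, 24)).astype(np.float32)
        b = rng.random((20, 24)).astype(np.float32)
        alone = predict(model, a)
        together = predict(model, np.stack([a, b]))[0]
        np.testing.assert_allclose(alone, together, atol=1e-6)

    def test_unet_training_mode_batch_dependent(self, rng):
        model = build_model(NetworkSpec(variant="unet", depth=2, channels=4), seed=0)
        a = rng.random((16, 16)).astype(np.float32)
        b = rng.random((16, 16)).astype(np.float32)
        pa = model.forward(a[None], training=True)[0]
        pab = model.forward(np.stack([a, b]), training=True)[0]
        assert not np.allclose(pa, pab)

    def test_spec_in_shape_mismatch_names_both(self, rng):
        spec = NetworkSpec(variant="sunet", depth=2, channels=4, in_shape=(16, 16))
        model = build_model(spec, seed=0)
        with pytest.raises(ValueError, match=r"\(20, 24\).*\(16, 16\)"):
            predict(model, rng.random((1, 20, 24)))


class TestGradients:
    @pytest.mark.parametrize("variant", ["sunet", "sunet_dropout", "unet", "unet_dc"])
    def test_backward_matches_finite_differences(self, variant):
        old = net.DTYPE
        net.DTYPE = "float64"
        try:
            rng = np.random.default_rng(0)
            model = build_model(NetworkSpec(variant=variant, depth=2, channels=3), seed=1)
            for _, arr, _, _ in model.params():
                arr += rng.normal(0, 0.05, arr.shape)  # move off kink manifolds
            x = rng.random((2, 9, 10))
            y = rng.random((2, 9, 10)) > 0.5
            state0 = model._drop_rng.bit_generator.state

            def loss():
                model._drop_rng.bit_generator.state = state0
                return soft_dice_loss(model.forward(x, training=True), y, 0.1)

            model._drop_rng.bit_generator.state = state0
            p = model.forward(x, training=True)
            model.backward(soft_dice_loss_grad(p, y, 0.1))
            probes = []
            for name, arr, grad, _ in model.params():
                flat, gflat = arr.reshape(-1), grad.copy().reshape(-1)
                for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    old_v, eps = flat[i], 1e-6
                    flat[i] = old_v + eps
                    lp = loss()
                    flat[i] = old_v - eps
                    lm = loss()
                    flat[i] = old_v
                    num = (lp - lm) / (2 * eps)
                    probes.append(abs(num - gflat[i]) / max(1e-4, abs(num), abs(gflat[i])))
            probes = np.array(probes)
            # rare probes may straddle an activation kink; the bulk must match tightly
            assert np.median(probes) < 1e-6
            assert np.quantile(probes, 0.95) < 1e-4
        finally:
            net.DTYPE = old


class TestSelfNormalization:
    def test_iterated_selu_layers_keep_moments(self, rng):
        x = rng.standard_normal((10_000, 64))
        for _ in range(20):
            w = rng.normal(0, 1 / np.sqrt(x.shape[1]), size=(x.shape[1], 64))
            x = selu(x @ w)
            assert -0.2 <= x.mean() <= 0.2
            assert 0.7 <= x.var() <= 1.3


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        spec = NetworkSpec(variant="unet", depth=2, channels=4)
        model = build_model(spec, seed=3)
        x = rng.random((1, 16, 16)).astype(np.float32)
        p0 = predict(model, x)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.spec == spec
        np.testing.assert_array_equal(predict(loaded, x), p0)
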