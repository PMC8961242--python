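"""Conditional adversarial network: architecture contracts, losses,
training smoke behaviour and whole-volume stitching."""

import numpy as np
import pytest

from adir import gan
from adir.data import VolumeChannelStack
from adir.nn import Adam
from adir.pipeline import make_cohort

TINY = dict(depth=3, base_filters=4, patch_edge=32, epochs=1, samples_per_epoch=2,
            batch_size=2, augment=False, disc_base_filters=4, disc_stages=2)


class TestGenerator:
    def test_shape_contract_depth5(self):
        cfg = gan.NetworkConfig(depth=5, base_filters=4, patch_edge=32)
        g = gan.build_generator(cfg, seed=0)
        x = np.zeros((1, 3, 32, 32, 32), np.float32)
        y = g.forward(x, train=False)
        assert y.shape == (1, 1, 32, 32, 32)

    def test_inference_determinism(self, rng):
        cfg = gan.NetworkConfig(depth=3, base_filters=4, patch_edge=16)
        g = gan.build_generator(cfg, seed=1)
        x = rng.normal(size=(1, 3, 16, 16, 16)).astype(np.float32)
        assert np.array_equal(g.forward(x, train=False), g.forward(x, train=False))

    def test_output_bounded(self, rng):
        cfg = gan.NetworkConfig(depth=2, base_filters=4, patch_edge=16)
        g = gan.build_generator(cfg, seed=2)
        x = (10 * rng.normal(size=(1, 3, 16, 16, 16))).astype(np.float32)
        y = g.forward(x, train=False)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_indivisible_extent_rejected(self):
        cfg = gan.NetworkConfig(depth=3, base_filters=4, patch_edge=16)
        g = gan.build_generator(cfg, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            g.forward(np.zeros((1, 3, 18, 18, 18), np.float32))

    def test_parameter_count_oracle(self):
        """Hand-computed layer-by-layer count for depth 2, base 4, in 2, k 3."""
        cfg = gan.NetworkConfig(depth=2, base_filters=4, kernel=3, in_channels=2,
                                patch_edge=16)
        g = gan.build_generator(cfg, seed=0)
        # enc0: conv 2->4 (2*27+1)*4 + IN 2*4
        # enc1: conv 4->8 stride 2 (4*27+1)*8 + IN 2*8
        # dec0: conv (8+4)->4 (12*27+1)*4 + IN 2*4
        # head: conv 4->1 (4*27+1)*1
        expected = (2 * 27 + 1) * 4 + 8 + (4 * 27 + 1) * 8 + 16 + (12 * 27 + 1) * 4 + 8 + (4 * 27 + 1)
        assert expected == 2533
        assert sum(p.data.size for p in g.parameters()) == expected


class TestDiscriminator:
    def test_score_map_range_and_extent(self, rng):
        cfg = gan.NetworkConfig(depth=3, base_filters=4, patch_edge=32,
                                disc_base_filters=4, disc_stages=3)
        d = gan.build_discriminator(cfg, seed=0)
        x = rng.normal(size=(1, 3, 32, 32, 32)).astype(np.float32)
        y = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        v = d.score(x, y, train=False)
        assert 0.0 < v.min() and v.max() < 1.0
        assert all(o < 32 for o in v.shape[2:])

    def test_shape_mismatch_rejected(self, rng):
        cfg = gan.NetworkConfig(depth=3, base_filters=4, patch_edge=32)
        d = gan.build_discriminator(cfg, seed=0)
        x = np.zeros((1, 3, 32, 32, 32), np.float32)
        y = np.zeros((1, 1, 16, 16, 16), np.float32)
        with pytest.raises(ValueError):
            d.score(x, y)

    def test_receptive_field_recurrence(self):
        """Closed form equals the backward recurrence r <- r*s + (k - s)."""
        kernels, strides = [4, 4, 4, 4], [2, 2, 2, 1]
        r = 1
        for k, s in zip(reversed(kernels), reversed(strides)):
            r = r * s + (k - s)
        assert gan.receptive_field(kernels, strides) == r == 46
        cfg = gan.NetworkConfig(disc_stages=3, disc_kernel=4)
        assert gan.build_discriminator(cfg, seed=0).receptive_field_ == 46


class TestLosses:
    def test_generator_loss_closed_form(self, rng):
        fake = rng.normal(size=(2, 1, 4, 4, 4))
        v = np.full((2, 1, 2, 2, 2), 0.5)
        # fake == real: reconstruction term vanishes, BCE(0.5) = ln 2
        assert gan.generator_loss(v, fake, fake, 10.0) == pytest.approx(np.log(2.0))

    def test_generator_loss_lambda_zero(self, rng):
        fake = rng.normal(size=(1, 1, 2, 2, 2))
        real = rng.normal(size=(1, 1, 2, 2, 2))
        v = rng.uniform(0.1, 0.9, size=(1, 1, 1, 1, 1))
        assert gan.generator_loss(v, fake, real, 0.0) == pytest.approx(gan.bce_loss(v, 1.0))

    def test_losses_match_direct_recomputation(self, rng):
        fake = rng.normal(size=(2, 1, 2, 2, 2))
        real = rng.normal(size=(2, 1, 2, 2, 2))
        v_f = rng.uniform(0.05, 0.95, size=(2, 1, 2, 2, 2))
        v_r = rng.uniform(0.05, 0.95, size=(2, 1, 2, 2, 2))
        lam = 3.7
        expect_g = float(np.mean(-np.log(v_f))) + lam * float(np.mean(np.abs(fake - real)))
        assert gan.generator_loss(v_f, fake, real, lam) == pytest.approx(expect_g, abs=1e-6)
        expect_d = 0.5 * (float(np.mean(-np.log(v_r))) + float(np.mean(-np.log(1 - v_f))))
        assert gan.discriminator_loss(v_r, v_f) == pytest.approx(expect_d, abs=1e-6)

    def test_discriminator_loss_endpoints(self):
        half = np.full((1, 1, 2, 2, 2), 0.5)
        assert gan.discriminator_loss(half, half) == pytest.approx(np.log(2.0))
        ones = np.full_like(half, 1.0)
        zeros = np.full_like(half, 0.0)
        assert gan.discriminator_loss(ones, zeros) == pytest.approx(0.0, abs=1e-5)


class TestTraining:
    def test_smoke_contract(self):
        cfg = gan.NetworkConfig(**TINY)
        cohort = make_cohort(2, (32, 32, 32), (1, 1, 1), 2, (1.0, 1.6), 0.0, seed=3)
        gen, hist = gan.train([s for _, s in cohort], cfg, seed=0)
        assert len(hist.g_mae) == len(hist.g_adv) == len(hist.d_loss) == 1
        assert np.isfinite(hist.g_mae + hist.g_adv + hist.d_loss).all()

    def test_epoch_size_guard(self):
        cfg = gan.NetworkConfig(depth=3, base_filters=4, patch_edge=32, epochs=1,
                                batch_size=2, augment=False)
        cohort = make_cohort(1, (32, 32, 32), (1, 1, 1), 0, (1.0, 1.6), 0.0, seed=3)
        # one small subject: the brain-voxel formula floors to zero samples
        with pytest.raises(ValueError, match="samples_per_epoch"):
            gan.train([s for _, s in cohort], cfg, seed=0)

    def test_discriminator_separates_frozen_generator(self, rng):
        """Trained against a frozen random generator, the discriminator's
        loss must fall below the chance level ln 2."""
        cfg = gan.NetworkConfig(depth=3, base_filters=4, patch_edge=16,
                                disc_base_filters=4, disc_stages=2)
        frozen = gan.build_generator(cfg, seed=99)
        disc = gan.build_discriminator(cfg, seed=7)
        opt = Adam(disc.parameters(), lr=2e-3, beta1=0.5, beta2=0.999)
        x = rng.normal(size=(2, 3, 16, 16, 16)).astype(np.float32)
        real = np.tanh(x[:, :1] * 0.5 + 0.2).astype(np.float32)
        fake = frozen.forward(x, train=False)
        losses = []
        for _ in range(30):
            opt.zero_grad()
            v_r = disc.score(x, real, train=True)
            disc.backward(0.5 * gan._bce_grad(v_r, 1.0))
            v_f = disc.score(x, fake, train=True)
            disc.backward(0.5 * gan._bce_grad(v_f, 0.0))
            opt.step()
            losses.append(gan.discriminator_loss(v_r, v_f))
        assert losses[-1] < np.log(2.0)


class TestPredictVolume:
    def test_no_overlap_equals_per_tile(self, rng):
        cfg = gan.NetworkConfig(depth=2, base_filters=4, patch_edge=16)
        g = gan.build_generator(cfg, seed=5)
        pred = rng.normal(size=(3, 32, 16, 16)).astype(np.float32)
        stack = VolumeChannelStack(predictors=pred, target=None, spacing=(1, 1, 1),
                                   mask=np.ones((32, 16, 16), np.uint8))
        out = gan.predict_volume(g, stack, 16, 16)
        tile0 = g.forward(pred[None, :, :16], train=False)[0, 0]
        tile1 = g.forward(pred[None, :, 16:], train=False)[0, 0]
        assert np.allclose(out[:16], tile0, atol=1e-6)
        assert np.allclose(out[16:], tile1, atol=1e-6)

    def test_constant_generator(self, rng):
        stack = VolumeChannelStack(
            predictors=rng.normal(size=(3, 24, 24, 24)).astype(np.float32),
            target=None, spacing=(1, 1, 1), mask=np.ones((24, 24, 24), np.uint8))
        out = gan.predict_volume(lambda p: np.zeros(p.shape[1:]), stack, 16, 8)
        assert np.all(out == 0.0)

    def test_half_stride_matches_naive_overlap_average(self, rng):
        """Sliding-window averaging equals a brute-force per-window oracle."""
        fn = lambda p: p[0] * 0.3 - p[1] ** 2  # deterministic patch function
        pred = rng.normal(size=(3, 24, 24, 24)).astype(np.float32)
        stack = VolumeChannelStack(predictors=pred, target=None, spacing=(1, 1, 1),
                                   mask=np.ones((24, 24, 24), np.uint8))
        S, stride = 16, 8
        out = gan.predict_volume(fn, stack, S, stride)

        padded = np.pad(pred, ((0, 0), (0, 0), (0, 0), (0, 0)))
        acc = np.zeros((24, 24, 24))
        wgt = np.zeros((24, 24, 24))
        starts = [0, 8]  # (24 - 16) / 8 covers the volume exactly
        for i in starts:
            for j in starts:
                for k in starts:
                    win = padded[:, i:i + S, j:j + S, k:k + S]
                    acc[i:i + S, j:j + S, k:k + S] += fn(win)
                    wgt[i:i + S, j:j + S, k:k + S] += 1
        expect = np.clip(acc / wgt, -1, 1)
        assert np.abs(out - expect).max() < 1e-6

    def test_stride_validation(self, rng):
        stack = VolumeChannelStack(
            predictors=rng.normal(size=(3, 16, 16, 16)).astype(np.float32),
            target=None, spacing=(1, 1, 1), mask=np.ones((16, 16, 16), np.uint8))
        with pytest.raises(ValueError):
            gan.predict_volume(lambda p: p[0], stack, 16, 24)


class TestCheckpointAndEstimator:
    def test_save_load_roundtrip(self, tmp_path, rng):
        cfg = gan.NetworkConfig(depth=2, base_filters=4, patch_edge=16)
        g = gan.build_generator(cfg, seed=3)
        path = tmp_path / "gen.npz"
        gan.save_generator(g, path)
        g2 = gan.load_generator(path)
        x = rng.normal(size=(1, 3, 16, 16, 16)).astype(np.float32)
        assert np.array_equal(g.forward(x, train=False), g2.forward(x, train=False))
        assert g2.config.depth == 2

    def test_estimator_params_roundtrip(self):
        model = gan.DirGan(depth=3, base_filters=8, random_state=1)
        params = model.get_params()
        assert params["depth"] == 3 and params["random_state"] == 1
        model.set_params(epochs=2)
        assert model.epochs == 2
        with pytest.raises(ValueError):
            model.set_params(bogus=1)
        with pytest.raises(RuntimeError):
            model.predict([])

    def test_estimator_fit_predict(self):
        cohort = make_cohort(2, (32, 32, 32), (1, 1, 1), 2, (1.0, 1.6), 0.0, seed=4)
        model = gan.DirGan(random_state=0, **TINY)
        model.fit([s for _, s in cohort])
        assert len(model.history_.g_mae) == 1
        preds = model.predict([cohort[0][1]])
        assert preds[0].shape == (32, 32, 32)
        assert np.isfinite(preds[0]).all()
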