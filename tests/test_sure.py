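"""MC-SURE loss identities, U-Net construction and desk-scale training."""

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from mridenoise import (
    ComplexImage,
    NoiseModel,
    PhantomSpec,
    SureConfig,
    add_gaussian_noise,
    apply_scale,
    build_sure_unet,
    denoise_sure,
    generate_phantom_slice,
    mc_sure_loss,
    mse_supervised,
    train_sure,
)
from mridenoise.complex_space import ParameterError


def box_blur(batch: np.ndarray) -> np.ndarray:
    """Explicit 3x3 box-blur operating per channel (a fixed linear denoiser)."""
    out = np.empty_like(batch)
    for n in range(batch.shape[0]):
        for c in range(2):
            out[n, c] = uniform_filter(batch[n, c], size=3, mode="constant")
    return out


def blur_matrix(h: int, w: int) -> np.ndarray:
    """Brute-force dense matrix of box_blur on a (2, h, w) sample."""
    k = 2 * h * w
    cols = []
    for idx in range(k):
        e = np.zeros((1, 2, h, w))
        e.ravel()[idx] = 1.0
        cols.append(box_blur(e).ravel())
    return np.array(cols).T


class TestConfig:
    def test_paper_defaults(self):
        cfg = SureConfig()
        assert (cfg.depth, cfg.kernel_size, cfg.base_features) == (5, 3, 48)
        assert (cfg.batch_size, cfg.epochs, cfg.learning_rate) == (10, 300, 3e-4)

    def test_validation(self):
        with pytest.raises(ParameterError):
            SureConfig(depth=0)
        with pytest.raises(ParameterError):
            SureConfig(epsilon=0.0)
        with pytest.raises(ParameterError):
            SureConfig(sigma=-1.0)


class TestUNet:
    @pytest.mark.parametrize("size", [(64, 64), (96, 96), (64, 96), (80, 80)])
    def test_output_shape_matches_input(self, size):
        cfg = SureConfig(depth=2, base_features=4, sigma=1.0)
        model = build_sure_unet(cfg)
        x = np.random.default_rng(0).normal(size=(1, 2, *size))
        assert model.net.apply(x).shape == x.shape

    def test_non_divisible_size_padded_and_cropped(self):
        cfg = SureConfig(depth=3, base_features=4, sigma=1.0)
        model = build_sure_unet(cfg)
        x = np.random.default_rng(0).normal(size=(1, 2, 44, 52))  # not /8
        assert model.net.apply(x).shape == x.shape

    def test_descriptor_round_trips_through_checkpoint(self, tmp_path):
        from mridenoise import load_checkpoint, save_checkpoint

        cfg = SureConfig(depth=1, base_features=4, sigma=0.5, seed=3)
        model = build_sure_unet(cfg)
        model.train_scale = 500.0
        save_checkpoint(model, tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        assert loaded.architecture == model.architecture
        assert loaded.train_scale == 500.0
        x = np.random.default_rng(1).normal(size=(1, 2, 16, 16))
        assert np.allclose(loaded.net.apply(x), model.net.apply(x))


class TestMseSupervised:
    def test_identical_is_zero(self, rng):
        b = rng.normal(size=(3, 2, 8, 8))
        assert mse_supervised(b, b) == 0.0

    def test_single_pixel_squared_modulus(self):
        pred = np.zeros((1, 2, 1, 1))
        truth = np.zeros((1, 2, 1, 1))
        pred[0, 0, 0, 0], pred[0, 1, 0, 0] = 3.0, 4.0
        assert mse_supervised(pred, truth) == 25.0

    def test_mean_over_batch(self, rng):
        a = rng.normal(size=(1, 2, 4, 4))
        b = rng.normal(size=(1, 2, 4, 4))
        z = np.zeros_like(a)
        la = mse_supervised(a, z)
        lb = mse_supervised(b, z)
        both = mse_supervised(np.concatenate([a, b]), np.concatenate([z, z]))
        assert np.isclose(both, (la + lb) / 2)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            mse_supervised(rng.normal(size=(1, 2, 4, 4)), rng.normal(size=(1, 2, 5, 5)))


class TestMcSureLoss:
    def test_identity_denoiser_estimates_k_sigma_sq(self):
        rng = np.random.default_rng(0)
        sigma, h, w = 1.0, 32, 32
        k = 2 * h * w
        vals = [
            mc_sure_loss(lambda a: a, rng.normal(0, sigma, (1, 2, h, w)), sigma,
                         epsilon=1e-3, seed=s)
            for s in range(100)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - k * sigma**2) < 4 * se

    def test_zero_denoiser_on_pure_noise_estimates_zero(self):
        rng = np.random.default_rng(1)
        sigma = 1.0
        vals = [
            mc_sure_loss(lambda a: np.zeros_like(a),
                         rng.normal(0, sigma, (1, 2, 16, 16)), sigma, 1e-3, seed=s)
            for s in range(150)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_divergence_term_matches_trace_oracle(self):
        """MC divergence of an explicit linear filter equals 2 sigma^2 tr(A)."""
        rng = np.random.default_rng(2)
        sigma, h, w = 1.0, 8, 8
        tr = np.trace(blur_matrix(h, w))
        eps = 1e-4
        divs = []
        for s in range(300):
            y = rng.normal(size=(1, 2, h, w))
            probe = np.random.default_rng(s).normal(size=y.shape)
            d = (probe * (box_blur(y + eps * probe) - box_blur(y))).sum() / eps
            divs.append(2 * sigma**2 * d)
        se = np.std(divs) / np.sqrt(len(divs))
        assert abs(np.mean(divs) - 2 * sigma**2 * tr) < 3 * se

    def test_epsilon_invariance_for_linear_denoiser(self):
        """Expected loss is flat in epsilon over [1e-4, 1e-2] x data scale."""
        rng = np.random.default_rng(3)
        sigma = 1.0
        means = []
        for eps in (1e-4, 1e-3, 1e-2):
            vals = [
                mc_sure_loss(box_blur, rng.normal(0, sigma, (1, 2, 16, 16)),
                             sigma, eps, seed=s)
                for s in range(100)
            ]
            means.append((np.mean(vals), np.std(vals) / np.sqrt(len(vals))))
        for (m1, s1), (m2, s2) in [(means[0], means[1]), (means[0], means[2])]:
            assert abs(m1 - m2) < 3 * np.hypot(s1, s2)

    def test_epsilon_zero_rejected(self, rng):
        with pytest.raises(ParameterError):
            mc_sure_loss(lambda a: a, rng.normal(size=(1, 2, 8, 8)), 1.0, 0.0)


class TestTraining:
    def test_zero_epochs_is_identity(self, rng):
        cfg = SureConfig(depth=1, base_features=4, epochs=0, sigma=0.1)
        model = build_sure_unet(cfg)
        w0 = [p.data.copy() for p in model.params()]
        x = rng.normal(size=(4, 2, 16, 16))
        model, history = train_sure(model, x, cfg)
        assert history == []
        assert all(np.array_equal(a, p.data) for a, p in zip(w0, model.params()))

    def test_desk_training_beats_noisy_and_descends(self):
        """A small SURE net trained briefly on noisy phantoms must beat the
        noisy input on a held-out slice, with a (weakly) descending loss."""
        spec = PhantomSpec(size=48, n_slices=1, n_subjects=10, seed=21)
        scale, sigma_raw = 1 / 2000.0, 150.0
        sigma = sigma_raw * scale
        slices = [
            apply_scale(generate_phantom_slice(spec, s, 0), scale) for s in range(10)
        ]
        noisy = [
            add_gaussian_noise(im, NoiseModel(sigma, seed=i))
            for i, im in enumerate(slices)
        ]
        cfg = SureConfig(depth=2, base_features=12, batch_size=4, epochs=20,
                         learning_rate=3e-3, sigma=sigma, seed=5)
        model = build_sure_unet(cfg)
        model, history = train_sure(model, noisy[:8], cfg)
        assert len(history) == 20
        assert np.median(history[-5:]) <= np.median(history[:5])
        held_truth, held_noisy = slices[9], noisy[9]
        out = denoise_sure(model, held_noisy)
        err_out = np.mean(np.abs(out.data - held_truth.data) ** 2)
        err_noisy = np.mean(np.abs(held_noisy.data - held_truth.data) ** 2)
        assert err_out < err_noisy

    def test_sigma_zero_training_approaches_identity(self):
        """With sigma = 0 the SURE loss reduces to reconstruction error, whose
        optimum is the identity map; a short run should get close to it."""
        spec = PhantomSpec(size=32, n_slices=1, n_subjects=8, seed=3)
        slices = [
            apply_scale(generate_phantom_slice(spec, s, 0), 1 / 2000.0)
            for s in range(8)
        ]
        cfg = SureConfig(depth=1, base_features=8, batch_size=4, epochs=40,
                         learning_rate=3e-3, sigma=0.0, seed=1)
        model = build_sure_unet(cfg)
        model, _ = train_sure(model, slices, cfg)
        out = denoise_sure(model, slices[0])
        power = np.mean(np.abs(slices[0].data) ** 2)
        rel = np.mean(np.abs(out.data - slices[0].data) ** 2) / power
        assert rel < 0.05

    def test_denoise_deterministic(self, rng):
        cfg = SureConfig(depth=1, base_features=4, sigma=0.1)
        model = build_sure_unet(cfg)
        model.train_scale = 1.0
        img = ComplexImage(rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16)))
        a, b = denoise_sure(model, img), denoise_sure(model, img)
        assert np.array_equal(a.data, b.data)

    def test_scale_mismatch_warns(self, rng):
        cfg = SureConfig(depth=1, base_features=4, sigma=0.1)
        model = build_sure_unet(cfg)
        model.train_stats = {"median_magnitude": 1.0}
        big = ComplexImage(1e4 * (rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))))
        with pytest.warns(RuntimeWarning, match="scale"):
            denoise_sure(model, big)
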