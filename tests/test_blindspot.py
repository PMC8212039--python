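"""Blindspot architecture contract, NLL loss, posterior mean, training."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from mridenoise import (
    BlindspotConfig,
    ComplexImage,
    GaussianPrior,
    NoiseModel,
    PhantomSpec,
    add_gaussian_noise,
    apply_scale,
    blindspot_train_loss,
    build_blindspot_net,
    denoise_blindspot,
    generate_phantom_slice,
    magnitude,
    posterior_mean,
    predict_prior,
    train_blindspot,
)
from mridenoise.complex_space import ParameterError, to_channels


def center_sensitivity(net, x: np.ndarray) -> float:
    """Max |change at pixel p| over perturbations of the input at p."""
    mu0, var0 = net.apply(x)
    worst = 0.0
    for i in range(x.shape[2]):
        for j in range(x.shape[3]):
            xp = x.copy()
            xp[0, :, i, j] += 1.0
            mu1, var1 = net.apply(xp)
            dev = max(
                np.abs(mu1[0, :, i, j] - mu0[0, :, i, j]).max(),
                np.abs(var1[0, :, i, j] - var0[0, :, i, j]).max(),
            )
            worst = max(worst, dev)
    return worst


@pytest.fixture(scope="module")
def trained_tiny_blindspot():
    """Blindspot net trained briefly on noisy 48x48 phantoms (shared)."""
    spec = PhantomSpec(size=48, n_slices=1, n_subjects=12, seed=31)
    scale, sigma_raw = 1 / 2000.0, 150.0
    sigma = sigma_raw * scale
    slices = [apply_scale(generate_phantom_slice(spec, s, 0), scale) for s in range(12)]
    noisy = [
        add_gaussian_noise(im, NoiseModel(sigma, seed=i)) for i, im in enumerate(slices)
    ]
    cfg = BlindspotConfig(depth=2, base_features=12, batch_size=4, epochs=25,
                          learning_rate=3e-3, lr_patience=5, sigma=sigma, seed=8)
    model = build_blindspot_net(cfg)
    model, history = train_blindspot(model, noisy[:10], cfg)
    return model, history, slices, noisy, sigma, sigma_raw


class TestArchitecture:
    def test_center_pixel_exclusion_untrained(self):
        cfg = BlindspotConfig(depth=2, base_features=8, sigma=0.1, seed=3)
        net = build_blindspot_net(cfg).net
        x = np.random.default_rng(0).normal(size=(1, 2, 16, 16))
        assert center_sensitivity(net, x) < 1e-6

    def test_center_pixel_exclusion_trained(self, trained_tiny_blindspot):
        model = trained_tiny_blindspot[0]
        x = np.random.default_rng(1).normal(size=(1, 2, 16, 16))
        assert center_sensitivity(model.net, x) < 1e-6

    def test_every_offcenter_neighbor_influences_output(self):
        cfg = BlindspotConfig(depth=2, base_features=8, sigma=0.1, seed=4)
        net = build_blindspot_net(cfg).net
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 2, 16, 16))
        mu0, _ = net.apply(x)
        ci = cj = 8
        for di in range(-2, 3):
            for dj in range(-2, 3):
                if di == 0 and dj == 0:
                    continue
                xp = x.copy()
                xp[0, :, ci + di, cj + dj] += 1.0
                mu1, _ = net.apply(xp)
                assert np.abs(mu1[0, :, ci, cj] - mu0[0, :, ci, cj]).max() > 1e-12

    def test_validation(self):
        with pytest.raises(ParameterError):
            BlindspotConfig(depth=0)
        with pytest.raises(ParameterError):
            BlindspotConfig(lr_patience=0)


def test_checkpoint_round_trip(tmp_path):
    from mridenoise import load_checkpoint, save_checkpoint

    cfg = BlindspotConfig(depth=1, base_features=4, sigma=0.3, seed=6)
    model = build_blindspot_net(cfg)
    model.train_scale = 1 / 2000.0
    save_checkpoint(model, tmp_path / "b.npz")
    loaded = load_checkpoint(tmp_path / "b.npz")
    assert loaded.architecture == model.architecture
    x = np.random.default_rng(0).normal(size=(1, 2, 16, 16))
    mu_a, var_a = model.net.apply(x)
    mu_b, var_b = loaded.net.apply(x)
    assert np.allclose(mu_a, mu_b) and np.allclose(var_a, var_b)


class TestLoss:
    def test_zero_at_perfect_prediction_unit_variance(self, rng):
        y = ComplexImage(rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8)))
        yc = to_channels(y)
        sigma = 0.6
        var = np.full_like(yc, 1.0 - sigma**2)
        prior = GaussianPrior(mu=yc.copy(), var=var)
        assert abs(blindspot_train_loss(prior, y, sigma)) < 1e-12

    def test_quadratic_term_linearity(self, rng):
        yc = np.zeros((2, 8, 8))
        y = ComplexImage(np.zeros((8, 8), dtype=complex))
        prior1 = GaussianPrior(mu=np.full_like(yc, 1.0), var=np.full_like(yc, 0.75))
        prior2 = GaussianPrior(mu=np.full_like(yc, np.sqrt(2.0)), var=np.full_like(yc, 0.75))
        sigma = 0.5  # var + sigma^2 = 1 -> log term identical
        l1 = blindspot_train_loss(prior1, y, sigma)
        l2 = blindspot_train_loss(prior2, y, sigma)
        assert np.isclose(l2 - l1, (2.0 - 1.0) / 2.0)

    def test_minimizers_match_calculus(self):
        """argmin_mu is y; argmin_var is (y-mu)^2 - sigma^2 when positive."""
        yv, sigma = 1.7, 0.4

        def loss_mu(mu):
            v = 0.3 + sigma**2
            return 0.5 * np.log(v) + (yv - mu) ** 2 / (2 * v)

        assert abs(minimize_scalar(loss_mu, bounds=(-10, 10), method="bounded").x - yv) < 1e-5

        mu = 0.2

        def loss_var(v):
            t = v + sigma**2
            return 0.5 * np.log(t) + (yv - mu) ** 2 / (2 * t)

        best = minimize_scalar(loss_var, bounds=(1e-9, 20), method="bounded").x
        assert abs(best - ((yv - mu) ** 2 - sigma**2)) < 1e-5


class TestPosteriorMean:
    def test_hand_example(self):
        pr = GaussianPrior(mu=np.full((2, 8, 8), 10.0), var=np.full((2, 8, 8), 4.0))
        y = ComplexImage(np.full((8, 8), 20.0 + 20.0j))
        out = posterior_mean(pr, y, 2.0)  # sigma^2 = 4
        assert np.allclose(out.data, 15.0 + 15.0j)

    def test_sigma_zero_returns_y_exactly(self, random_complex_image):
        yc = to_channels(random_complex_image)
        pr = GaussianPrior(mu=np.zeros_like(yc), var=np.full_like(yc, 0.5))
        out = posterior_mean(pr, random_complex_image, 0.0)
        assert np.array_equal(out.data, random_complex_image.data)

    def test_vanishing_variance_returns_mu(self, random_complex_image):
        yc = to_channels(random_complex_image)
        pr = GaussianPrior(mu=np.full_like(yc, 2.5), var=np.full_like(yc, 1e-12))
        out = posterior_mean(pr, random_complex_image, 1.0)
        assert np.allclose(out.data, 2.5 + 2.5j, atol=1e-10)

    def test_matches_numerical_integration(self):
        """Closed form vs quadrature of the 1-D conjugate posterior."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            mu, var = rng.normal(), rng.uniform(0.05, 4.0)
            yv, sigma = rng.normal(scale=2), rng.uniform(0.05, 2.0)
            dens = lambda x: np.exp(
                -((yv - x) ** 2) / (2 * sigma**2) - (x - mu) ** 2 / (2 * var)
            )
            lo, hi = min(mu, yv) - 12, max(mu, yv) + 12
            num = quad(lambda x: x * dens(x), lo, hi)[0] / quad(dens, lo, hi)[0]
            closed = (mu * sigma**2 + yv * var) / (var + sigma**2)
            assert abs(num - closed) < 1e-6

    def test_convex_combination_property(self, rng):
        yc = rng.normal(size=(2, 8, 8))
        mu = rng.normal(size=(2, 8, 8))
        var = rng.uniform(0.01, 5.0, size=(2, 8, 8))
        pr = GaussianPrior(mu=mu, var=var)
        y = ComplexImage(yc[0] + 1j * yc[1])
        out = to_channels(posterior_mean(pr, y, 0.8))
        assert np.all(out <= np.maximum(mu, yc) + 1e-12)
        assert np.all(out >= np.minimum(mu, yc) - 1e-12)


class TestTraining:
    def test_posterior_beats_noisy_on_held_out(self, trained_tiny_blindspot):
        model, _, slices, noisy, sigma, sigma_raw = trained_tiny_blindspot
        errs_out, errs_noisy = [], []
        for truth, obs in zip(slices[10:], noisy[10:]):
            out = denoise_blindspot(model, obs, sigma)
            errs_out.append(np.mean(np.abs(out.data - truth.data) ** 2))
            errs_noisy.append(np.mean(np.abs(obs.data - truth.data) ** 2))
        assert np.mean(errs_out) < np.mean(errs_noisy)

    def test_lr_history_non_increasing(self, trained_tiny_blindspot):
        history = trained_tiny_blindspot[1]
        lrs = history["lr"]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_variance_larger_at_edges_than_flat_interior(self, trained_tiny_blindspot):
        """The learned prior is confident in flat tissue, uncertain at edges —
        the mechanism behind blindspot edge preservation."""
        model, _, slices, noisy, sigma, _ = trained_tiny_blindspot
        edge_vars, flat_vars = [], []
        for truth, obs in zip(slices[10:], noisy[10:]):
            prior = predict_prior(model, obs)
            tm = magnitude(truth)
            gy, gx = np.gradient(tm)
            gm = np.hypot(gy, gx)
            interior = tm > 0
            edge = (gm > 0.25 * gm.max()) & interior
            flat = (gm < 0.02 * gm.max()) & interior
            if edge.any() and flat.any():
                v = prior.var.mean(axis=0)
                edge_vars.append(np.median(v[edge]))
                flat_vars.append(np.median(v[flat]))
        assert np.median(flat_vars) < np.median(edge_vars)

    def test_constant_image_parameter_recovery(self):
        """On x = c with noise sigma, the trained prior mean recovers c.

        Per-pixel precision is floor-limited by receptive-field averaging
        (a context of N noisy pixels cannot beat sigma/sqrt(N)), so the
        recovery claim is asserted on the interior bias of mu.
        """
        c, sigma = 1.0, 0.25
        rng = np.random.default_rng(9)
        imgs = [
            ComplexImage(np.full((16, 16), c + 0j) + rng.normal(0, sigma, (16, 16))
                         + 1j * rng.normal(0, sigma, (16, 16)))
            for _ in range(10)
        ]
        cfg = BlindspotConfig(depth=3, base_features=8, batch_size=8, epochs=600,
                              learning_rate=3e-3, lr_patience=600, sigma=sigma, seed=2)
        model = build_blindspot_net(cfg)
        model, _ = train_blindspot(model, imgs[:9], cfg)
        prior = predict_prior(model, imgs[9])
        interior = prior.mu[0, 6:-6, 6:-6]  # real channel, away from borders
        assert abs(interior.mean() - c) < 0.05 * sigma

    def test_zero_epochs_returns_empty_history(self, rng):
        cfg = BlindspotConfig(depth=1, base_features=4, epochs=0, sigma=0.1)
        model = build_blindspot_net(cfg)
        model, history = train_blindspot(model, rng.normal(size=(4, 2, 16, 16)), cfg)
        assert history["train_loss"] == []

    def test_denoise_deterministic_and_sigma_zero_passthrough(self, trained_tiny_blindspot):
        model, _, _, noisy, sigma, _ = trained_tiny_blindspot
        obs = noisy[10]
        a = denoise_blindspot(model, obs, sigma)
        b = denoise_blindspot(model, obs, sigma)
        assert np.array_equal(a.data, b.data)
        ident = denoise_blindspot(model, obs, 0.0)
        assert np.array_equal(ident.data, obs.data)
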