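"""Reverse-diffusion reconstruction: schedule, steps, post-processing."""

import numpy as np
import pytest

import pogmdm as pg
from pogmdm.recon import (DiffusionSchedule, ReconConfig, intensity_correction,
                          langevin_step_size, run_algorithm1, tv_charbonnier,
                          zeta_at)
from pogmdm.sense import KSpaceData


class TestSchedule:
    def test_endpoint_values(self):
        sched = DiffusionSchedule()
        assert np.isclose(zeta_at(1.0, sched), 10.0)
        assert np.isclose(zeta_at(0.0, sched), 0.001)

    def test_geometric_midpoint(self):
        # at (1 - t/T)^p = 1/2 the level is 10 * (1e-4)^(1/2) = 0.1
        sched = DiffusionSchedule()
        t = 1.0 - 0.5 ** (1.0 / 5.0)
        assert np.isclose(zeta_at(t, sched), 0.1, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            zeta_at(1.5, DiffusionSchedule())

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DiffusionSchedule(zeta_min=1.0, zeta_max=0.5)
        with pytest.raises(ValueError):
            DiffusionSchedule(t0=0.0)


class TestLangevinStepSize:
    def test_zero_r_gives_zero(self, rng):
        eps, _ = langevin_step_size(0.0, np.ones((4, 4)), rng)
        assert eps == 0.0

    def test_ratio_identity(self, rng):
        # a score field with ||s||^2 = 2 ||xi||^2 yields eps = r exactly
        xi_probe = np.random.default_rng(11).standard_normal((8, 8))
        score = np.sqrt(2.0) * xi_probe
        eps, xi = langevin_step_size(0.3, score,
                                     np.random.default_rng(11), eps_max=None)
        assert np.allclose(xi, xi_probe)
        assert np.isclose(eps, 0.3)

    def test_expected_step_size(self):
        # E ||xi||^2 = d, so E[eps] = 2 r d / ||score||^2
        d = 32 * 32
        score = np.full((32, 32), 2.0)
        r = 0.1
        rng = np.random.default_rng(0)
        vals = [langevin_step_size(r, score, rng, eps_max=None)[0]
                for _ in range(4000)]
        expected = 2 * r * d / np.sum(score ** 2)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_zero_score_falls_back_with_warning(self, rng):
        with pytest.warns(UserWarning):
            eps, _ = langevin_step_size(0.2, np.zeros((4, 4)), rng,
                                        eps_max=0.7)
        assert eps == 0.7

    def test_eps_max_caps_the_step(self, rng):
        eps, _ = langevin_step_size(10.0, np.full((8, 8), 1e-8), rng,
                                    eps_max=1.0)
        assert eps == 1.0


class TestIntensityCorrection:
    def test_unit_rss_is_identity(self, rng):
        x = rng.random((4, 4))
        s = np.ones((1, 4, 4), complex)
        assert np.allclose(intensity_correction(x, s), x)

    def test_cancels_constant_real_scaling(self, rng):
        x = rng.random((4, 4))
        s = rng.normal(size=(3, 4, 4)) + 1j * rng.normal(size=(3, 4, 4))
        b = 1.7
        assert np.allclose(intensity_correction(x * b, s / b),
                           intensity_correction(x, s), atol=1e-12)

    def test_matches_loop(self, rng):
        x = rng.random((4, 4))
        s = rng.normal(size=(2, 4, 4)) + 1j * rng.normal(size=(2, 4, 4))
        expected = x * np.sqrt(np.abs(s[0]) ** 2 + np.abs(s[1]) ** 2)
        assert np.allclose(intensity_correction(x, s), expected, atol=1e-12)


class TestTvCharbonnier:
    def test_constant_image_value(self):
        lam, eps = 2.0, 0.01
        val, grad = tv_charbonnier(np.full((5, 5), 3.0), lam, eps)
        assert np.isclose(val, lam * 25 * eps)
        assert np.allclose(grad, 0.0, atol=1e-14)

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.normal(size=(6, 6))
        lam, eps_tv = 1.3, 0.05
        _, grad = tv_charbonnier(x, lam, eps_tv)
        h = 1e-6
        fd = np.zeros_like(x)
        for i in range(6):
            for j in range(6):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += h
                xm[i, j] -= h
                fd[i, j] = (tv_charbonnier(xp, lam, eps_tv)[0]
                            - tv_charbonnier(xm, lam, eps_tv)[0]) / (2 * h)
        assert np.max(np.abs(grad - fd)) / np.max(np.abs(fd)) < 1e-5

    def test_linear_in_lambda(self, rng):
        x = rng.normal(size=(5, 5))
        v1, _ = tv_charbonnier(x, 1.0, 0.01)
        v3, _ = tv_charbonnier(x, 3.0, 0.01)
        assert np.isclose(v3, 3 * v1, rtol=1e-12)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            tv_charbonnier(np.zeros((3, 3)), 1.0, 0.0)


@pytest.fixture(scope="module")
def tiny_problem():
    """32x32 joint problem with a quick marginal-fit prior."""
    size = 32
    phantom = pg.make_phantom(pg.PhantomSpec(shape=(size, size), seed=2))
    coils = pg.make_coils(4, (size, size), seed=2)
    mask = pg.make_mask("cartesian", size, size, 3.0, 0.1, seed=2)
    y, truth = pg.simulate_acquisition(phantom, coils, mask, 0.01,
                                       np.random.default_rng(2))
    model = pg.desk_prior((size, size), n_train_images=6, seed=2)
    sched = DiffusionSchedule(steps=250)
    return phantom, coils, mask, y, model, sched


class TestRunAlgorithm:
    def test_deterministic_under_seed(self, tiny_problem):
        phantom, coils, mask, y, model, sched = tiny_problem
        cfg = ReconConfig(n_samples=1, seed=4)
        yn = KSpaceData(y.y / np.max(pg.zero_filled_rss(y)), mask)
        x1, s1 = run_algorithm1(yn, mask, model, sched, cfg,
                                np.random.default_rng(4))
        x2, s2 = run_algorithm1(yn, mask, model, sched, cfg,
                                np.random.default_rng(4))
        assert np.array_equal(x1, x2) and np.array_equal(s1, s2)

    def test_noiseless_fully_sampled_with_true_coils(self):
        """Data consistency dominates: near-exact recovery (> 40 dB)."""
        size = 32
        phantom = pg.make_phantom(pg.PhantomSpec(shape=(size, size), seed=5))
        coils = pg.make_coils(4, (size, size), seed=5)
        full = pg.make_mask("full", size, size)
        y, _ = pg.simulate_acquisition(phantom, coils, full, 0.0,
                                       np.random.default_rng(5))
        model = pg.desk_prior((size, size), n_train_images=6, seed=5)
        sched = DiffusionSchedule(steps=1000)
        cfg = ReconConfig(r=0.0, n_samples=1, seed=0, update_coils=False)
        scale = float(np.max(pg.zero_filled_rss(y)))
        yn = KSpaceData(y.y / scale, full)
        import pogmdm.recon as R
        orig = R._initialize
        R._initialize = lambda yy, mm, cc, ss, rr: (
            orig(yy, mm, cc, ss, rr)[0], coils.astype(complex))
        try:
            x, _ = run_algorithm1(yn, full, model, sched, cfg,
                                  np.random.default_rng(6))
        finally:
            R._initialize = orig
        assert pg.psnr(np.abs(x) * scale, phantom) > 40.0

    def test_single_coil_real_mode_contract(self, tiny_problem):
        """s = 1, coil updates off, real iterates: the single-coil pipeline
        configuration — sensitivities untouched, iterates purely real."""
        size = 32
        phantom = pg.make_phantom(pg.PhantomSpec(shape=(size, size), seed=3))
        mask = pg.make_mask("cartesian", size, size, 3.0, 0.1, seed=3)
        y, _ = pg.simulate_acquisition(phantom, np.ones((1, size, size)),
                                       mask, 0.02, np.random.default_rng(3))
        model = tiny_problem[4]
        sched = tiny_problem[5]
        cfg = ReconConfig(n_samples=1, seed=0, update_coils=False,
                          real_only=True)
        yn = KSpaceData(y.y / np.max(pg.zero_filled_rss(y)), mask)
        x, s = run_algorithm1(yn, mask, model, sched, cfg,
                              np.random.default_rng(1))
        assert np.allclose(s, 1.0)
        assert np.allclose(x.imag, 0.0)
        assert np.all(np.isfinite(x.real))

    def test_mmse_variance_contract(self, tiny_problem):
        phantom, coils, mask, y, model, sched = tiny_problem
        cfg = ReconConfig(n_samples=2, seed=0)
        mean, var, stack = pg.mmse_and_variance(y, mask, model, sched, cfg)
        assert stack.shape[0] == 2
        assert np.all(var >= 0)
        assert np.allclose(mean, stack.mean(axis=0))
        single = ReconConfig(n_samples=1, seed=0)
        _, var1, _ = pg.mmse_and_variance(y, mask, model, sched, single)
        assert np.allclose(var1, 0.0)

    def test_default_sample_count_is_25(self):
        assert ReconConfig().n_samples == 25
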