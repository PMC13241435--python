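"""SENSE forward model, likelihood gradients, masks, noise, HDF5 layout."""

import numpy as np
import pytest

import pogmdm as pg
from pogmdm.sense import (KSpaceData, SamplingMask, add_noise, fft2c,
                          grad_s_loglik, grad_x_loglik, ifft2c,
                          load_kspace_h5, make_mask, save_kspace_h5,
                          sense_forward, zero_filled_rss)


@pytest.fixture
def toy(rng):
    h = w = 4
    x = rng.normal(size=(h, w)) + 1j * rng.normal(size=(h, w))
    s = rng.normal(size=(2, h, w)) + 1j * rng.normal(size=(2, h, w))
    mask = make_mask("cartesian", h, w, 2.0, 0.25, seed=0)
    return x, s, mask


class TestForward:
    def test_single_coil_full_mask_is_plain_dft(self, rng):
        x = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        full = make_mask("full", 4, 4)
        y = sense_forward(x, np.ones((1, 4, 4)), full)
        assert np.allclose(y.y[0], fft2c(x), atol=1e-12)

    def test_scaling_ambiguity_exact(self, toy, rng):
        x, s, mask = toy
        b = rng.uniform(0.5, 2.0, size=x.shape) * np.exp(1j * rng.uniform(0, 1, x.shape))
        y1 = sense_forward(x, s, mask)
        y2 = sense_forward(x * b, s / b, mask)
        assert np.allclose(y1.y, y2.y, atol=1e-12)

    def test_matches_index_loop(self, toy):
        x, s, mask = toy
        y = sense_forward(x, s, mask)
        h, w = x.shape
        F = np.exp(-2j * np.pi * np.outer(np.arange(h), np.arange(h)) / h) / np.sqrt(h)
        for i in range(2):
            direct = F @ (s[i] * x) @ F.T
            assert np.allclose(y.y[i], mask.mask * direct, atol=1e-10)

    def test_off_mask_exactly_zero(self, toy):
        x, s, mask = toy
        y = sense_forward(x, s, mask)
        assert np.all(y.y[:, mask.mask == 0] == 0)

    def test_shape_mismatch(self, toy):
        x, s, mask = toy
        with pytest.raises(ValueError):
            sense_forward(x, s[:, :2], mask)


def _neg_half_sq(x, s, y, mask):
    r = y.y - mask.mask * fft2c(s * x[None])
    return -0.5 * float(np.sum(np.abs(r) ** 2))


class TestLikelihoodGradients:
    def test_zero_at_consistent_data(self, toy):
        x, s, mask = toy
        y = sense_forward(x, s, mask)
        assert np.max(np.abs(grad_x_loglik(x, s, y, mask))) < 1e-12
        assert np.max(np.abs(grad_s_loglik(x, s, y, mask))) < 1e-12

    def test_grad_x_matches_finite_differences(self, toy, rng):
        x, s, mask = toy
        y = sense_forward(x, s, mask)
        yd = KSpaceData(y.y + mask.mask * (rng.normal(size=y.y.shape)
                                           + 1j * rng.normal(size=y.y.shape)),
                        mask)
        g = grad_x_loglik(x, s, yd, mask)
        eps = 1e-6
        fd = np.zeros_like(x)
        for i in range(4):
            for j in range(4):
                d = np.zeros_like(x)
                d[i, j] = eps
                re = (_neg_half_sq(x + d, s, yd, mask)
                      - _neg_half_sq(x - d, s, yd, mask)) / (2 * eps)
                im = (_neg_half_sq(x + 1j * d, s, yd, mask)
                      - _neg_half_sq(x - 1j * d, s, yd, mask)) / (2 * eps)
                fd[i, j] = re + 1j * im
        assert np.max(np.abs(g - fd)) / np.max(np.abs(fd)) < 1e-5

    def test_grad_s_matches_finite_differences(self, toy, rng):
        x, s, mask = toy
        y = sense_forward(x, s, mask)
        yd = KSpaceData(y.y + mask.mask * (rng.normal(size=y.y.shape)
                                           + 1j * rng.normal(size=y.y.shape)),
                        mask)
        g = grad_s_loglik(x, s, yd, mask)
        eps = 1e-6
        fd = np.zeros_like(s)
        for c in range(2):
            for i in range(4):
                for j in range(4):
                    d = np.zeros_like(s)
                    d[c, i, j] = eps
                    re = (_neg_half_sq(x, s + d, yd, mask)
                          - _neg_half_sq(x, s - d, yd, mask)) / (2 * eps)
                    im = (_neg_half_sq(x, s + 1j * d, yd, mask)
                          - _neg_half_sq(x, s - 1j * d, yd, mask)) / (2 * eps)
                    fd[c, i, j] = re + 1j * im
        assert np.max(np.abs(g - fd)) / np.max(np.abs(fd)) < 1e-5

    def test_single_coil_full_mask_classical_residual(self, rng):
        x = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        full = make_mask("full", 4, 4)
        s = np.ones((1, 4, 4), dtype=complex)
        yd = KSpaceData(fft2c(x) + rng.normal(size=(1, 4, 4)), full)
        g = grad_x_loglik(x, s, yd, full)
        assert np.allclose(g, ifft2c(yd.y[0] - fft2c(x)), atol=1e-12)

    def test_adjoint_identity(self, toy, rng):
        x, s, mask = toy
        u = mask.mask * (rng.normal(size=(2, 4, 4)) + 1j * rng.normal(size=(2, 4, 4)))
        Ax = sense_forward(x, s, mask).y
        lhs = np.vdot(Ax, u)
        AHu = np.sum(np.conj(s) * ifft2c(mask.mask * u), axis=0)
        rhs = np.vdot(x, AHu)
        assert abs(lhs - rhs) < 1e-10

    def test_dft_unitarity(self, rng):
        x = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        assert np.max(np.abs(ifft2c(fft2c(x)) - x)) < 1e-12


class TestMasks:
    def test_full(self):
        m = make_mask("full", 6, 8)
        assert m.e == 48 and m.achieved_acceleration == 1.0

    def test_acl_column_count(self):
        m = make_mask("cartesian", 16, 368, 4.0, 0.08)
        row = np.fft.fftshift(m.mask[0])
        # contiguous central block of ceil(0.08*368) = 30 columns
        center = row[368 // 2 - 15:368 // 2 + 15]
        assert center.sum() == 30

    def test_acl_block_covers_dc(self):
        m = make_mask("cartesian", 8, 64, 4.0, 0.08)
        assert m.mask[0, 0] == 1  # DC is inside the ACL block

    @pytest.mark.parametrize("kind,accel", [
        ("cartesian", 4.0), ("cartesian_rotated", 4.0), ("radial", 6.0),
        ("spiral", 5.0), ("gaussian2d", 8.0),
    ])
    def test_achieved_acceleration_within_ten_percent(self, kind, accel):
        m = make_mask(kind, 64, 64, accel, 0.08, seed=3)
        assert abs(m.achieved_acceleration - accel) / accel < 0.10

    def test_rotated_transposes_pattern(self):
        m = make_mask("cartesian", 32, 32, 4.0, 0.08)
        mr = make_mask("cartesian_rotated", 32, 32, 4.0, 0.08)
        assert np.array_equal(m.mask.T, mr.mask)

    def test_gaussian_center_denser_than_edge(self):
        centers, edges = [], []
        for seed in range(100):
            m = np.fft.fftshift(make_mask("gaussian2d", 32, 32, 6.0,
                                          seed=seed).mask)
            centers.append(m[12:20, 12:20].mean())
            edges.append(m[:4, :4].mean())
        assert np.mean(centers) > np.mean(edges)

    def test_determinism_under_seed(self):
        a = make_mask("gaussian2d", 32, 32, 6.0, seed=9).mask
        b = make_mask("gaussian2d", 32, 32, 6.0, seed=9).mask
        assert np.array_equal(a, b)

    def test_infeasible_rate_rejected(self):
        with pytest.raises(ValueError):
            make_mask("cartesian", 16, 64, 64.0, 0.5)

    def test_mask_projection_idempotent(self):
        m = make_mask("cartesian", 8, 8, 2.0, 0.25)
        y = np.random.default_rng(0).normal(size=(8, 8))
        once = m.mask * y
        assert np.array_equal(m.mask * once, once)


class TestZeroFilledRss:
    def test_recovers_real_nonnegative_image(self, rng):
        x = np.abs(rng.normal(size=(8, 8)))
        full = make_mask("full", 8, 8)
        y = sense_forward(x, np.ones((1, 8, 8)), full)
        assert np.allclose(zero_filled_rss(y), x, atol=1e-10)

    def test_nonnegative_and_matches_loop(self, toy):
        x, s, mask = toy
        y = sense_forward(x, s, mask)
        got = zero_filled_rss(y)
        assert np.all(got >= 0)
        expected = np.sqrt(sum(np.abs(ifft2c(y.y[i])) ** 2 for i in range(2)))
        assert np.allclose(got, expected, atol=1e-12)


class TestNoise:
    def test_zero_sigma_is_identity(self, toy, rng):
        x, s, mask = toy
        y = sense_forward(x, s, mask)
        assert np.array_equal(add_noise(y, 0.0, rng).y, y.y)

    def test_component_std_matches_sigma(self, rng):
        """Empirical per-component std over ~1e5 sampled entries within 2%."""
        mask = make_mask("full", 128, 128)
        y = KSpaceData(np.zeros((8, 128, 128), complex), mask)
        noisy = add_noise(y, 0.02, rng)
        assert abs(noisy.y.real.std() - 0.02) / 0.02 < 0.02
        assert abs(noisy.y.imag.std() - 0.02) / 0.02 < 0.02

    def test_off_mask_stays_zero(self, toy, rng):
        x, s, mask = toy
        y = add_noise(sense_forward(x, s, mask), 0.05, rng)
        assert np.all(y.y[:, mask.mask == 0] == 0)

    def test_negative_sigma_rejected(self, toy, rng):
        x, s, mask = toy
        with pytest.raises(ValueError):
            add_noise(sense_forward(x, s, mask), -0.1, rng)


class TestHdf5:
    def test_roundtrip(self, toy, tmp_path, rng):
        x, s, mask = toy
        y = add_noise(sense_forward(x, s, mask), 0.01, rng)
        path = tmp_path / "k.h5"
        save_kspace_h5(path, y, extras={"truth_image": np.abs(x)})
        back = load_kspace_h5(path)
        assert np.allclose(back.y, y.y, atol=1e-12)
        assert np.array_equal(back.mask.mask, mask.mask)
        assert back.mask.kind == "cartesian"
        assert np.isclose(back.sigma_n, 0.01)
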