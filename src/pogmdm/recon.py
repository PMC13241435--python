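"""Joint image + coil-sensitivity reconstruction by reverse diffusion.

One iteration of the sampler runs, in order:

1. predictor — Euler-Maruyama step of the reverse variance-exploding SDE,
   with the prior score applied separately to the real and imaginary parts;
2. data consistency — a lambda-weighted ascent step on the log-likelihood
   in the image;
3. corrector — M annealed-Langevin steps with the norm-matched step size
   ``eps = 2 r ||xi||^2 / ||score||^2``;
4. coil update — a likelihood ascent step on the sensitivities followed by
   the DST-diagonalized smoothing map with trade-off ``mu``.

The geometric noise schedule is ``zeta(t) = zeta_max (zeta_min/zeta_max)^
((1 - t/T)^p)`` and the prior is queried at the diffusion time
``tau = zeta^2 / 2`` whose marginal perturbation std equals ``zeta``.
Reconstruction starts from the zero-filled estimate at the reduced time
``t0`` (default ``0.2 T``), so only ``N t0 / T`` of the ``N`` grid steps run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coils import prox_coil
from .model import PoGMDMModel
from .sense import (KSpaceData, SamplingMask, grad_s_loglik, grad_x_loglik,
                    ifft2c, zero_filled_rss)

__all__ = ["DiffusionSchedule", "ReconConfig", "zeta_at",
           "langevin_step_size", "run_algorithm1", "mmse_and_variance",
           "intensity_correction", "tv_charbonnier"]


@dataclass
class DiffusionSchedule:
    zeta_min: float = 0.001
    zeta_max: float = 10.0
    p: float = 5.0
    horizon: float = 1.0          # T
    steps: int = 1000             # N
    t0: float = 0.2               # reduced reverse-diffusion starting time

    def __post_init__(self) -> None:
        if not 0 < self.zeta_min < self.zeta_max:
            raise ValueError("need 0 < zeta_min < zeta_max")
        if self.p <= 0 or self.steps < 1 or not 0 < self.t0 <= self.horizon:
            raise ValueError("invalid schedule parameters")

    def zeta(self, t: float) -> float:
        return zeta_at(t, self)


def zeta_at(t: float, schedule: DiffusionSchedule) -> float:
    """Geometric noise level at schedule time ``t`` in ``[0, T]``."""
    T = schedule.horizon
    if not 0 <= t <= T:
        raise ValueError(f"t={t} outside [0, {T}]")
    ratio = schedule.zeta_min / schedule.zeta_max
    return schedule.zeta_max * ratio ** ((1.0 - t / T) ** schedule.p)


def langevin_step_size(r: float, score_field: np.ndarray,
                       rng: np.random.Generator, eps_max: float | None = None):
    """Norm-matched Langevin step: ``2 r ||xi||^2 / ||score||^2``.

    Returns ``(eps, xi)`` with ``xi`` the standard-normal field whose norm
    set the step; the caller reuses ``xi`` as the injected noise.  A
    vanishing score norm falls back to ``eps_max`` with a warning, and any
    ``eps_max`` also caps the step (the norm-matched rule diverges when the
    score is much weaker than the rule presumes).
    """
    xi = rng.standard_normal(score_field.shape)
    denom = float(np.vdot(score_field, score_field).real)
    if denom == 0.0:
        import warnings
        warnings.warn("zero score norm; falling back to eps_max")
        return (eps_max if eps_max is not None else 0.0) if r > 0 else 0.0, xi
    eps = 2.0 * r * float(np.sum(xi * xi)) / denom
    if eps_max is not None:
        eps = min(eps, eps_max)
    return eps, xi


@dataclass
class ReconConfig:
    lam: float = 1.0              # data-consistency weight
    mu: float = 1.0               # coil smoothing trade-off (grid searched)
    r: float = 0.005              # Langevin step-size factor (grid searched)
    corrector_steps: int = 1      # M
    eps_max: float = 1.0          # cap / fallback for the Langevin step
    n_samples: int = 25           # MMSE sample count
    seed: int = 0
    update_coils: bool = True
    real_only: bool = False       # single-coil real-valued mode
    final_denoise: bool = True    # Tweedie step after the last iteration

    def __post_init__(self) -> None:
        if min(self.lam, self.mu, self.r) < 0 or self.corrector_steps < 0:
            raise ValueError("lam, mu, r must be >= 0 and M >= 0")


def _complex_score(model: PoGMDMModel, x: np.ndarray, tau: float,
                   real_only: bool) -> np.ndarray:
    sr = model.score(np.ascontiguousarray(x.real), tau)
    if real_only:
        return sr.astype(complex)
    si = model.score(np.ascontiguousarray(x.imag), tau)
    return sr + 1j * si


def _initialize(y: KSpaceData, mask: SamplingMask, config: ReconConfig,
                schedule: DiffusionSchedule, rng: np.random.Generator):
    coil_images = ifft2c(y.y)
    rss = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))
    if config.update_coils:
        s = prox_coil(coil_images / (rss + 0.05 * rss.max() + 1e-12),
                      config.mu)
    else:
        s = np.ones_like(coil_images)
    x = np.sum(np.conj(s) * coil_images, axis=0).astype(complex)
    z0 = schedule.zeta(schedule.t0)
    noise = rng.standard_normal(x.shape)
    if config.real_only:
        x = x.real + z0 * noise + 0j
    else:
        x = x + z0 * (noise + 1j * rng.standard_normal(x.shape))
    return x, s


def run_algorithm1(y: KSpaceData, mask: SamplingMask, model: PoGMDMModel,
                   schedule: DiffusionSchedule, config: ReconConfig,
                   rng: np.random.Generator | None = None):
    """Predictor-corrector joint reconstruction; returns ``(image, coils)``."""
    rng = rng or np.random.default_rng(config.seed)
    T, N = schedule.horizon, schedule.steps
    i_start = max(1, int(round(N * schedule.t0 / T)))
    x, s = _initialize(y, mask, config, schedule, rng)
    for i in range(i_start, 0, -1):
        t_i = T * i / N
        t_im1 = T * (i - 1) / N
        zi, zim1 = schedule.zeta(t_i), schedule.zeta(t_im1)
        tau = 0.5 * zi ** 2
        dvar = zi ** 2 - zim1 ** 2
        # predictor (reverse VE SDE, Euler-Maruyama)
        sc = _complex_score(model, x, tau, config.real_only)
        noise = rng.standard_normal(x.shape)
        if not config.real_only:
            noise = noise + 1j * rng.standard_normal(x.shape)
        x = x + dvar * sc + np.sqrt(dvar) * noise
        # data consistency
        x = x + config.lam * grad_x_loglik(x, s, y, mask)
        # corrector (annealed Langevin at the new level)
        tau_next = 0.5 * zim1 ** 2
        for _ in range(config.corrector_steps):
            sc = _complex_score(model, x, tau_next, config.real_only)
            eps, xi = langevin_step_size(config.r, sc.real, rng,
                                         eps_max=config.eps_max)
            if not config.real_only:
                xi = xi + 1j * rng.standard_normal(x.shape)
            x = x + eps * sc + np.sqrt(2.0 * eps) * xi
        if config.real_only:
            x = x.real + 0j
        # coil update: likelihood ascent then proximal smoothing
        if config.update_coils:
            s = s + config.lam * grad_s_loglik(x, s, y, mask)
            s = prox_coil(s, config.mu)
        if not (np.all(np.isfinite(x.real)) and np.all(np.isfinite(x.imag))):
            raise FloatingPointError(f"non-finite iterate at step {i}")
    if config.final_denoise:
        # return the expected clean image given the last iterate (Tweedie),
        # removing the residual noise injected by the last corrector step
        tau_end = 0.5 * schedule.zeta(0.0) ** 2
        x = x + 2.0 * tau_end * _complex_score(model, x, tau_end,
                                               config.real_only)
        x = x + config.lam * grad_x_loglik(x, s, y, mask)
        if config.real_only:
            x = x.real + 0j
    return x, s


def reconstruct_magnitude(y: KSpaceData, mask: SamplingMask,
                          model: PoGMDMModel, schedule: DiffusionSchedule,
                          config: ReconConfig,
                          rng: np.random.Generator | None = None):
    """Full pipeline: normalize by ||x_ZF||_inf, run, rescale, correct.

    Returns ``(magnitude image, coils)``.
    """
    xzf = zero_filled_rss(y)
    scale = float(np.max(xzf))
    if scale == 0:
        raise ValueError("zero-filled reconstruction is identically zero")
    y_n = KSpaceData(y.y / scale, y.mask, y.sigma_n / scale)
    x, s = run_algorithm1(y_n, mask, model, schedule, config, rng)
    mag = np.abs(x) * scale
    if config.update_coils:
        mag = intensity_correction(mag, s)
    return mag, s


def mmse_and_variance(y: KSpaceData, mask: SamplingMask, model: PoGMDMModel,
                      schedule: DiffusionSchedule, config: ReconConfig):
    """Monte-Carlo posterior mean and pixel-wise variance of the magnitude.

    Runs ``config.n_samples`` independent reconstructions with seeds spawned
    from ``config.seed``; returns ``(mean, variance, samples)`` where the
    variance is the unbiased estimator (zero when only one sample is drawn).
    """
    if config.n_samples < 1:
        raise ValueError("need at least one sample")
    root = np.random.SeedSequence(config.seed)
    samples = []
    for child in root.spawn(config.n_samples):
        rng = np.random.default_rng(child)
        mag, _ = reconstruct_magnitude(y, mask, model, schedule, config, rng)
        samples.append(mag)
    stack = np.stack(samples)
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1) if len(samples) > 1 else np.zeros_like(mean)
    return mean, var, stack


def intensity_correction(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Multiply by the RSS of the sensitivities; cancels the constant real
    scaling ambiguity of the forward model."""
    s = np.asarray(s)
    if s.ndim == 2:
        s = s[None]
    return np.asarray(x) * np.sqrt(np.sum(np.abs(s) ** 2, axis=0))


def tv_charbonnier(x: np.ndarray, lambda_tv: float, eps_tv: float):
    """Charbonnier-smoothed isotropic total variation and its gradient.

    ``TV(x) = lam sum_i sqrt(dv_i^2 + dh_i^2 + eps^2)`` with forward
    differences (replicated edge: zero difference at the last row/column),
    so a constant image has value ``lam * d * eps`` and zero gradient.
    """
    if eps_tv <= 0:
        raise ValueError("eps_tv must be positive")
    x = np.asarray(x, dtype=float)
    dv = np.zeros_like(x)
    dh = np.zeros_like(x)
    dv[:-1] = x[1:] - x[:-1]
    dh[:, :-1] = x[:, 1:] - x[:, :-1]
    root = np.sqrt(dv * dv + dh * dh + eps_tv * eps_tv)
    value = lambda_tv * float(np.sum(root))
    gv = dv / root
    gh = dh / root
    grad = np.zeros_like(x)
    grad[:-1] -= gv[:-1]
    grad[1:] += gv[:-1]
    grad[:, :-1] -= gh[:, :-1]
    grad[:, 1:] += gh[:, :-1]
    return value, lambda_tv * grad
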