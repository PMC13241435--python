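"""Reconstruction quality metrics and the coil null-space residual."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["psnr", "nmse", "ssim", "nullspace_residual", "PSNR_CAP"]

PSNR_CAP = 200.0  # sentinel for a pixel-perfect match


def _check(x, ref):
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    if not np.any(ref):
        raise ValueError("reference is identically zero")
    return x, ref


def psnr(x: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; peak = max of the reference."""
    x, ref = _check(x, ref)
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0:
        return PSNR_CAP
    return 10.0 * np.log10(ref.max() ** 2 / mse)


def nmse(x: np.ndarray, ref: np.ndarray) -> float:
    """``||x - ref||^2 / ||ref||^2`` (scale by 100 only when reporting)."""
    x, ref = _check(x, ref)
    return float(np.sum((x - ref) ** 2) / np.sum(ref ** 2))


def ssim(x: np.ndarray, ref: np.ndarray) -> float:
    """Structural similarity on the magnitude pair, 7x7 window, standard
    K1 = 0.01, K2 = 0.03 constants, data range = max of the reference."""
    x, ref = _check(x, ref)
    return float(structural_similarity(x, ref, win_size=7, K1=0.01, K2=0.03,
                                       data_range=float(ref.max())))


def nullspace_residual(coil_images: np.ndarray, s: np.ndarray,
                       rss_floor: float = 1e-8):
    """Per-coil null-space residuals of coil images w.r.t. sensitivities.

    ``res_i = s_i / |s|_RSS^2 * sum_j conj(s_j) x_j - x_i``; near zero when
    the coil images are exactly ``s_i * x`` for some image ``x``.  Returns
    ``(per-coil residual fields, RSS-over-coils residual map)``.  Pixels
    where the sensitivity RSS vanishes are masked to zero with a warning.
    """
    coil_images = np.asarray(coil_images, dtype=complex)
    s = np.asarray(s, dtype=complex)
    if coil_images.ndim == 2:
        coil_images = coil_images[None]
    if s.ndim == 2:
        s = s[None]
    rss2 = np.sum(np.abs(s) ** 2, axis=0)
    bad = rss2 <= rss_floor
    if np.any(bad):
        import warnings
        warnings.warn(f"{int(bad.sum())} pixels with vanishing coil RSS "
                      "masked out of the null-space residual")
    safe = np.where(bad, 1.0, rss2)
    combined = np.sum(np.conj(s) * coil_images, axis=0)
    res = s / safe * combined[None] - coil_images
    res[:, bad] = 0.0
    rss_res = np.sqrt(np.sum(np.abs(res) ** 2, axis=0))
    return res, rss_res
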