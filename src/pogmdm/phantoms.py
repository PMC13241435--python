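"""Synthetic data: phantoms, coil maps, acquisitions, GMM random fields.

These generators stand in for clinical magnitude images at desk scale: the
phantoms are piecewise-smooth ellipse composites (the reconstruction
algorithms care about edges and smooth regions, not anatomical fidelity),
the coil maps are smooth complex fields that taper to zero at the image
border with a root-sum-of-squares close to one on the support, and the GMM
random fields provide ground truth with known mixture weights for
training-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .sense import KSpaceData, SamplingMask, add_noise, sense_forward

__all__ = ["PhantomSpec", "make_phantom", "make_coils",
           "simulate_acquisition", "gmm_random_field"]


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (64, 64)
    n_components: int = 8
    edge_smoothness: float = 1.0   # Gaussian blur std in pixels
    seed: int = 0


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Piecewise-smooth nonnegative image with maximum value 1."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w),
                         indexing="ij")
    img = np.zeros(spec.shape)
    # background ellipse mimicking an anatomy outline
    img += 0.4 * (((yy / 0.85) ** 2 + (xx / 0.75) ** 2) <= 1.0)
    for _ in range(spec.n_components):
        cy, cx = rng.uniform(-0.55, 0.55, size=2)
        ry, rx = rng.uniform(0.08, 0.4, size=2)
        ang = rng.uniform(0, np.pi)
        amp = rng.uniform(-0.5, 0.9)
        yr = (yy - cy) * np.cos(ang) + (xx - cx) * np.sin(ang)
        xr = -(yy - cy) * np.sin(ang) + (xx - cx) * np.cos(ang)
        img += amp * ((yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0)
    if spec.edge_smoothness > 0:
        img = gaussian_filter(img, spec.edge_smoothness)
    img = np.clip(img, 0.0, None)
    m = img.max()
    if m == 0:
        img[h // 2, w // 2] = 1.0
        m = 1.0
    return img / m


def make_coils(c: int, shape: tuple[int, int], smoothness: float = 0.35,
               seed: int = 0) -> np.ndarray:
    """``c`` smooth complex sensitivities tapering to zero at the border.

    Coil centers sit on a circle outside the field of view; magnitudes are
    broad Gaussian bumps, phases are low-order random harmonics.  The set is
    normalized so the root sum of squares is ~1 inside the support (bounded
    well away from zero) while still vanishing toward the border.
    """
    if c < 1:
        raise ValueError("need at least one coil")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w),
                         indexing="ij")
    edge = (np.cos(np.pi / 2 * np.clip(np.abs(yy), 0, 1) ** 4)
            * np.cos(np.pi / 2 * np.clip(np.abs(xx), 0, 1) ** 4))
    # taper toward the border but keep a small floor so that every pixel
    # stays (weakly) observable through the forward model
    taper = 0.15 + 0.85 * edge
    coils = np.empty((c, h, w), dtype=complex)
    for i in range(c):
        ang = 2 * np.pi * i / c + rng.uniform(-0.2, 0.2)
        cy, cx = 1.3 * np.sin(ang), 1.3 * np.cos(ang)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mag = np.exp(-d2 / (2 * (2.0 * smoothness) ** 2))
        phase = (rng.uniform(-np.pi, np.pi)
                 + rng.uniform(-1, 1) * np.pi * yy
                 + rng.uniform(-1, 1) * np.pi * xx)
        coils[i] = mag * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(coils) ** 2, axis=0))
    coils = coils / rss * taper
    return coils


def simulate_acquisition(phantom: np.ndarray, coils: np.ndarray,
                         mask: SamplingMask, sigma_n: float,
                         rng: np.random.Generator):
    """Noisy SENSE acquisition; returns ``(KSpaceData, truth dict)``."""
    y = sense_forward(phantom, coils, mask)
    y = add_noise(y, sigma_n, rng)
    truth = {"image": np.asarray(phantom), "coils": np.asarray(coils)}
    return y, truth


def gmm_random_field(weights: np.ndarray, means: np.ndarray, sigma0_sq: float,
                     shape: tuple[int, int], rng: np.random.Generator
                     ) -> np.ndarray:
    """I.i.d. pixels from a 1D Gaussian mixture (identity-filter case)."""
    weights = np.asarray(weights, dtype=float)
    idx = rng.choice(weights.size, size=shape, p=weights / weights.sum())
    return np.asarray(means)[idx] + np.sqrt(sigma0_sq) * rng.standard_normal(shape)
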