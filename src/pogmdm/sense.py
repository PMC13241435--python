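"""Nonlinear SENSE acquisition model and k-space sampling masks.

Each coil measures the unitary 2D DFT of the image weighted by that coil's
complex sensitivity, restricted to a binary sampling mask:

    y_i = M F(s_i . x) + n_i .

Because both the image and the sensitivities are unknown the model is
nonlinear, with the well-known scaling ambiguity (x . b, s / b).  Gradients
follow the Wirtinger convention: the returned fields are the full real
gradients d/dRe + i d/dIm of the Gaussian log-likelihood, which are exact
ascent directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask", "KSpaceData", "fft2c", "ifft2c", "sense_forward",
    "grad_x_loglik", "grad_s_loglik", "make_mask", "zero_filled_rss",
    "add_noise", "save_kspace_h5", "load_kspace_h5",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary (orthonormal) 2D DFT over the last two axes."""
    return np.fft.fft2(x, norm="ortho")


def ifft2c(y: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(y, norm="ortho")


@dataclass
class SamplingMask:
    mask: np.ndarray
    kind: str = "full"
    acceleration: float = 1.0
    acl_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.all(np.isin(self.mask, (0, 1))):
            raise ValueError("mask entries must be binary")
        self.mask = self.mask.astype(np.uint8)
        if self.mask.sum() < 1:
            raise ValueError("mask samples no frequencies")

    @property
    def e(self) -> int:
        """Number of sampled spatial frequencies."""
        return int(self.mask.sum())

    @property
    def achieved_acceleration(self) -> float:
        return self.mask.size / self.e

    def apply(self, kspace: np.ndarray) -> np.ndarray:
        return kspace * self.mask


@dataclass
class KSpaceData:
    """Per-coil complex measurements, zero off the mask."""

    y: np.ndarray                      # (c, h, w) complex
    mask: SamplingMask
    sigma_n: float = 0.0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=complex)
        if self.y.ndim == 2:
            self.y = self.y[None]
        off = self.y * (1 - self.mask.mask)
        if np.any(off != 0):
            raise ValueError("k-space values off the mask must be zero")

    @property
    def n_coils(self) -> int:
        return self.y.shape[0]


def sense_forward(x: np.ndarray, s: np.ndarray,
                  mask: SamplingMask) -> KSpaceData:
    """Noise-free forward model: per coil ``mask * F(s_i * x)``."""
    x = np.asarray(x, dtype=complex)
    s = np.asarray(s, dtype=complex)
    if s.ndim == 2:
        s = s[None]
    if s.shape[1:] != x.shape:
        raise ValueError(f"coil shape {s.shape[1:]} != image {x.shape}")
    y = mask.mask * fft2c(s * x[None])
    return KSpaceData(y, mask)


def _residual(x, s, y, mask):
    return y.y - mask.mask * fft2c(s * x[None])


def grad_x_loglik(x: np.ndarray, s: np.ndarray, y: KSpaceData,
                  mask: SamplingMask) -> np.ndarray:
    """Ascent direction of -1/2 ||A(x,s) - y||^2 in the image."""
    x = np.asarray(x, dtype=complex)
    s = np.asarray(s, dtype=complex)
    if s.ndim == 2:
        s = s[None]
    r = _residual(x, s, y, mask)
    return np.sum(np.conj(s) * ifft2c(mask.mask * r), axis=0)


def grad_s_loglik(x: np.ndarray, s: np.ndarray, y: KSpaceData,
                  mask: SamplingMask) -> np.ndarray:
    """Ascent direction of -1/2 ||A(x,s) - y||^2 in the coil sensitivities.

    The exact Wirtinger gradient carries the conjugate of the image, and the
    finite-difference oracle confirms it; this is what is implemented.
    """
    x = np.asarray(x, dtype=complex)
    s = np.asarray(s, dtype=complex)
    if s.ndim == 2:
        s = s[None]
    r = _residual(x, s, y, mask)
    return np.conj(x)[None] * ifft2c(mask.mask * r)


def zero_filled_rss(y: KSpaceData, mask: SamplingMask | None = None) -> np.ndarray:
    """Root-sum-of-squares of the zero-filled coil images."""
    coil_images = ifft2c(y.y)
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))


def add_noise(y: KSpaceData, sigma_n: float,
              rng: np.random.Generator) -> KSpaceData:
    """Add i.i.d. complex Gaussian noise (std ``sigma_n`` per real/imag
    component) on the sampled locations only."""
    if sigma_n < 0:
        raise ValueError("sigma_n must be nonnegative")
    if sigma_n == 0:
        return KSpaceData(y.y.copy(), y.mask, 0.0)
    n = rng.normal(0, sigma_n, size=y.y.shape) \
        + 1j * rng.normal(0, sigma_n, size=y.y.shape)
    return KSpaceData(y.y + y.mask.mask * n, y.mask, sigma_n)


# ----------------------------------------------------------------------
# mask generators
# ----------------------------------------------------------------------

def _cartesian_columns(w: int, acceleration: float, acl_fraction: float):
    n_acl = int(np.ceil(acl_fraction * w))
    n_cols = int(round(w / acceleration))
    if n_cols < max(n_acl, 1):
        raise ValueError(
            f"infeasible rate: need {n_cols} columns but ACL block has {n_acl}")
    cols = np.zeros(w, dtype=np.uint8)
    lo = w // 2 - n_acl // 2   # block centered on the DC column (index w//2
    cols[lo:lo + n_acl] = 1    # in the centered layout, 0 after ifftshift)
    extra = n_cols - n_acl
    if extra > 0:
        free = np.flatnonzero(cols == 0)
        pick = free[np.round(np.linspace(0, free.size - 1, extra)).astype(int)]
        cols[pick] = 1
    return cols


def make_mask(kind: str, h: int, w: int, acceleration: float = 1.0,
              acl_fraction: float = 0.08, seed: int = 0) -> SamplingMask:
    """Binary sampling mask on the Cartesian grid.

    Kinds: ``full``; ``cartesian`` (equispaced phase-encode columns plus a
    contiguous central ACL block; ``cartesian_rotated`` transposes the
    pattern); ``radial`` (rasterized center-crossing lines); ``spiral``
    (rasterized Archimedean arms); ``gaussian2d`` (Bernoulli with
    center-peaked density and a fully sampled small center).  Non-Cartesian
    trajectories are realized as binary masks on the grid — no gridding.
    The achieved acceleration ``h*w/e`` is within ~10% of the target.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "full":
        m = np.ones((h, w), dtype=np.uint8)
    elif kind == "cartesian":
        # columns are laid out centered (ACL block around the k-space
        # center), then shifted to the unshifted-FFT convention (DC at 0)
        cols = np.fft.ifftshift(_cartesian_columns(w, acceleration,
                                                   acl_fraction))
        m = np.tile(cols[None, :], (h, 1))
    elif kind == "cartesian_rotated":
        rows = np.fft.ifftshift(_cartesian_columns(h, acceleration,
                                                   acl_fraction))
        m = np.tile(rows[:, None], (1, w))
    elif kind == "radial":
        m = _best_rate(lambda n: _radial(h, w, n), h * w / acceleration,
                       lo=1, hi=4 * (h + w))
    elif kind == "spiral":
        m = _best_rate(lambda n: _spiral(h, w, n, rng=np.random.default_rng(seed)),
                       h * w / acceleration, lo=1, hi=4 * (h + w))
    elif kind == "gaussian2d":
        m = _gaussian2d(h, w, acceleration, rng)
    else:
        raise ValueError(f"unknown mask kind {kind!r}")
    return SamplingMask(m, kind=kind, acceleration=acceleration,
                        acl_fraction=acl_fraction if "cartesian" in kind else 0.0,
                        seed=seed)


def _best_rate(builder, e_target: float, lo: int, hi: int) -> np.ndarray:
    """Bisection over the line/arm count to hit a target sample count."""
    best, best_err = None, np.inf
    while lo <= hi:
        mid = (lo + hi) // 2
        m = builder(mid)
        e = m.sum()
        err = abs(e - e_target)
        if err < best_err:
            best, best_err = m, err
        if e < e_target:
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def _radial(h: int, w: int, n_lines: int) -> np.ndarray:
    from skimage.draw import line
    m = np.zeros((h, w), dtype=np.uint8)
    cy, cx = h // 2, w // 2
    R = np.hypot(h, w)
    for ang in np.linspace(0, np.pi, n_lines, endpoint=False):
        dy, dx = np.sin(ang) * R, np.cos(ang) * R
        r0 = int(np.clip(cy - dy, 0, h - 1)), int(np.clip(cx - dx, 0, w - 1))
        r1 = int(np.clip(cy + dy, 0, h - 1)), int(np.clip(cx + dx, 0, w - 1))
        rr, cc = line(r0[0], r0[1], r1[0], r1[1])
        m[rr, cc] = 1
    return np.fft.ifftshift(m)


def _spiral(h: int, w: int, n_arms: int, rng, turns: float = 3.0) -> np.ndarray:
    m = np.zeros((h, w), dtype=np.uint8)
    cy, cx = h // 2, w // 2
    t = np.linspace(0, 1, int(40 * turns * max(h, w) / 64))
    theta = 2 * np.pi * turns * t
    rad = t * 0.5 * np.hypot(h, w) / np.sqrt(2)
    for arm in range(n_arms):
        phi = 2 * np.pi * arm / n_arms
        yy = np.clip(np.round(cy + rad * np.sin(theta + phi)), 0, h - 1)
        xx = np.clip(np.round(cx + rad * np.cos(theta + phi)), 0, w - 1)
        m[yy.astype(int), xx.astype(int)] = 1
    return np.fft.ifftshift(m)


def _gaussian2d(h: int, w: int, acceleration: float, rng) -> np.ndarray:
    yy, xx = np.meshgrid(np.arange(h) - h / 2, np.arange(w) - w / 2,
                         indexing="ij")
    d2 = (yy / h) ** 2 + (xx / w) ** 2
    dens = np.exp(-d2 / (2 * 0.12 ** 2))
    target = h * w / acceleration
    # fixed-point scaling so the clipped density integrates to the target
    scale = target / dens.sum()
    for _ in range(30):
        p = np.clip(scale * dens, 0, 1)
        if p.sum() == 0:
            break
        scale *= target / p.sum()
    p = np.clip(scale * dens, 0, 1)
    m = (rng.random((h, w)) < p).astype(np.uint8)
    c = max(2, min(h, w) // 32)
    m[h // 2 - c:h // 2 + c, w // 2 - c:w // 2 + c] = 1
    return np.fft.ifftshift(m)


# ----------------------------------------------------------------------
# HDF5 layout (fastMRI style)
# ----------------------------------------------------------------------

def save_kspace_h5(path, y: KSpaceData, extras: dict | None = None) -> None:
    """Write ``kspace`` (slices x coils x h x w), ``mask`` and metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=y.y[None].astype(np.complex128))
        f.create_dataset("mask", data=y.mask.mask.astype(np.uint8))
        f.attrs["trajectory"] = y.mask.kind
        f.attrs["acceleration"] = y.mask.acceleration
        f.attrs["acl_fraction"] = y.mask.acl_fraction
        f.attrs["sigma_n"] = y.sigma_n
        if y.mask.seed is not None:
            f.attrs["seed"] = y.mask.seed
        for key, val in (extras or {}).items():
            f.create_dataset(key, data=val)


def load_kspace_h5(path, slice_index: int = 0) -> KSpaceData:
    import h5py

    with h5py.File(path, "r") as f:
        k = np.asarray(f["kspace"])
        if k.ndim == 3:          # coils x h x w (single-slice layout)
            y = k
        else:
            y = k[slice_index]
        if "mask" in f:
            m = np.asarray(f["mask"])
        else:
            m = (np.abs(y).sum(axis=0) > 0).astype(np.uint8)
        mask = SamplingMask(m, kind=str(f.attrs.get("trajectory", "unknown")),
                            acceleration=float(f.attrs.get("acceleration", 1.0)),
                            acl_fraction=float(f.attrs.get("acl_fraction", 0.0)))
        return KSpaceData(y * mask.mask, mask,
                          sigma_n=float(f.attrs.get("sigma_n", 0.0)))
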