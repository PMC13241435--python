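"""Nonseparable shearlet filter bank.

The bank is generated from two small learnable kernels: a 1D low-pass
``h1`` (default length 9) and a 2D directional generator ``P`` (default
17 x 17).  Scales are carved out of the frequency axis by telescoping the
low-pass spectrum, directions by shearing the generator's transfer function,
and the frequency plane is split into a horizontal and a vertical cone
(the vertical-cone filters are transposes of the horizontal ones).

The construction is spectral: each filter is realized as a real, even
transfer function on the full image grid, consistent with circular boundary
conditions.  It follows the cone-adapted digital shearlet recipe in spirit
but is not a bit-for-bit reproduction of any particular reference system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bank import FilterBank

__all__ = ["ShearletConfig", "enumerate_shears", "build_shearlet_bank",
           "project_shearlet_params", "default_h1", "default_P"]


def default_h1() -> np.ndarray:
    """9-tap binomial low pass (DTFT = cos^8(w/2)); unit DC gain."""
    from math import comb
    h = np.array([comb(8, n) for n in range(9)], dtype=float)
    return h / h.sum()


def default_P() -> np.ndarray:
    """17 x 17 directional generator with DTFT cos^2(b/2) in the sheared axis.

    Only the central 1 x 3 block is nonzero at initialization; learning can
    populate the rest of the support.
    """
    P = np.zeros((17, 17))
    P[8, 7:10] = [0.25, 0.5, 0.25]
    return P


def project_shearlet_params(h1: np.ndarray, P: np.ndarray):
    """Renormalize ``h1`` to unit DC gain and ``P`` to unit Frobenius energy."""
    h1 = np.asarray(h1, dtype=float)
    P = np.asarray(P, dtype=float)
    dc = h1.sum()
    if abs(dc) < 1e-12:
        raise ValueError("h1 has (near) zero DC gain; cannot normalize")
    en = np.linalg.norm(P)
    if en < 1e-12:
        raise ValueError("P has (near) zero energy; cannot normalize")
    return h1 / dc, P / en


def enumerate_shears(j: int) -> list[tuple[int, int, str]]:
    """All (scale, shear, cone) labels for a ``j``-scale system.

    Every scale uses the maximal shear range ``|k| <= ceil(2^floor(j/2))``
    of the system, so the two-scale default has 5 shearings per scale and
    2 * 5 * 2 = 20 filters.  Reference parameter totals for other scale counts
    do not pin down the per-scale convention, so labels for ``j != 2`` follow
    the same rule but should be treated as a package convention.
    """
    if j < 1:
        raise ValueError(f"need at least one scale, got j={j}")
    K = int(np.ceil(2.0 ** (j // 2)))
    labels = []
    for scale in range(1, j + 1):
        for shear in range(-K, K + 1):
            for cone in ("h", "v"):
                labels.append((scale, shear, cone))
    return labels


@dataclass
class ShearletConfig:
    scales: int = 2
    grid_shape: tuple[int, int] = (64, 64)
    h1: np.ndarray = field(default_factory=default_h1)
    P: np.ndarray = field(default_factory=default_P)

    @property
    def labels(self) -> list[tuple[int, int, str]]:
        return enumerate_shears(self.scales)


def _dtft_1d(h: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """DTFT of a centered odd-length 1D kernel at arbitrary frequencies."""
    n = np.arange(h.size) - h.size // 2
    return np.tensordot(np.exp(-1j * omega[..., None] * n), h, axes=([-1], [0]))


def _dtft_2d(P: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """DTFT of a centered 2D kernel at per-pixel frequency pairs (a, b)."""
    m = np.arange(P.shape[0]) - P.shape[0] // 2
    n = np.arange(P.shape[1]) - P.shape[1] // 2
    Ea = np.exp(-1j * a[..., None] * m)          # (..., 17)
    Eb = np.exp(-1j * b[..., None] * n)          # (..., 17)
    return np.einsum("...m,mn,...n->...", Ea, P, Eb)


def build_shearlet_bank(config: ShearletConfig) -> FilterBank:
    """Construct the spectral filter bank from ``h1`` and ``P``.

    Scale bands telescope the squared low-pass spectrum so that the bands
    cover every nonzero frequency: with ``G = |DTFT h1|`` (unit DC),
    the finest band is ``sqrt(1 - G(w)^2)`` and each coarser band is
    ``prod finer-lowpass * sqrt(1 - G(2^m w)^2)``.  Shear ``k`` of scale band
    ``B`` in the horizontal cone has transfer
    ``B(w1) * |P^(w1, 2 w2 - k w1)|``; vertical-cone filters swap the axes.
    """
    h1, P = np.asarray(config.h1, float), np.asarray(config.P, float)
    if not np.any(h1) or not np.any(P):
        raise ValueError("degenerate (all-zero) shearlet generator")
    h1n, Pn = project_shearlet_params(h1, P)
    h, w = config.grid_shape
    w1 = 2 * np.pi * np.fft.fftfreq(h)[:, None] * np.ones((1, w))
    w2 = 2 * np.pi * np.fft.fftfreq(w)[None, :] * np.ones((h, 1))

    J = config.scales

    def G(om):
        return np.abs(_dtft_1d(h1n, om))

    def band(scale, om):
        # scale J is finest; coarser scales see dyadically stretched axes
        m = J - scale
        B = np.sqrt(np.maximum(1.0 - G(2.0 ** m * om) ** 2, 0.0))
        for mm in range(m):
            B = B * G(2.0 ** mm * om)
        return B

    spectra = []
    for scale, k, cone in config.labels:
        if cone == "h":
            a, b = w1, w2
        else:
            a, b = w2, w1
        wedge = np.abs(_dtft_2d(Pn, a, 2.0 * b - k * a))
        spectra.append(band(scale, a) * wedge)
    return FilterBank(spectra=np.stack(spectra), grid_shape=config.grid_shape,
                      learnable=True,
                      n_filter_params=h1.size + P.size)


def sharing_map_for(labels, strategy: str = "none") -> np.ndarray:
    """Factor -> weight-group map for the potential-sharing strategies.

    ``within``  shares mirrored shears inside each cone (|k| identifies the
    potential), ``across`` shares the two cones at equal shear, and ``both``
    combines them, leaving ``K + 1`` potentials per scale (3 for the
    two-scale default, hence 6 groups).
    """
    keys = []
    for scale, k, cone in labels:
        if strategy == "none":
            keys.append((scale, k, cone))
        elif strategy == "within":
            keys.append((scale, abs(k), cone))
        elif strategy == "across":
            keys.append((scale, k))
        elif strategy == "both":
            keys.append((scale, abs(k)))
        else:
            raise ValueError(f"unknown sharing strategy {strategy!r}")
    uniq = {}
    out = []
    for key in keys:
        if key not in uniq:
            uniq[key] = len(uniq)
        out.append(uniq[key])
    return np.array(out, dtype=int)
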