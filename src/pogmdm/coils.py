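"""Quadratic smoothness prior on coil sensitivities.

The penalty is ``gamma(s) = 1/2 sum_i (||D Re s_i||^2 + ||D Im s_i||^2)``
with ``D`` the forward-finite-difference operator under Dirichlet (zero
outside the image) boundary conditions, which encodes that sensitivities
vanish beyond the field of view.  Its proximal-type map is diagonalized by
the orthonormal DST-I, whose basis vectors are the eigenvectors of the
Dirichlet Laplacian ``D^T D``.

A note on the weight: the closed-form map implemented here,
``Q_mu(x) = S^T(S(mu x) / (tau + mu)) = mu (D^T D + mu I)^{-1} x``, is the
proximal map of ``gamma`` at weight ``1/mu`` rather than ``mu``; here
``mu`` is simply the single smoothing trade-off knob (larger ``mu`` ->
weaker smoothing).
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dstn, idstn

__all__ = ["gamma", "laplacian_eigs", "prox_coil", "dirichlet_diffs"]


def dirichlet_diffs(u: np.ndarray) -> list[np.ndarray]:
    """All forward differences of a real field, zero-padded outside.

    Includes both boundary terms (``u_1 - 0`` and ``0 - u_n``) in each
    direction, so that the normal operator is the Dirichlet Laplacian.
    """
    h, w = u.shape
    p = np.zeros((h + 2, w))
    p[1:-1] = u
    dv = p[1:] - p[:-1]
    q = np.zeros((h, w + 2))
    q[:, 1:-1] = u
    dh = q[:, 1:] - q[:, :-1]
    return [dv, dh]


def gamma(s: np.ndarray) -> float:
    """Smoothness penalty of a coil set (real and imaginary parts)."""
    s = np.asarray(s, dtype=complex)
    if s.ndim == 2:
        s = s[None]
    total = 0.0
    for coil in s:
        for part in (coil.real, coil.imag):
            total += sum(float(np.sum(d * d)) for d in dirichlet_diffs(part))
    return 0.5 * total


def laplacian_eigs(h: int, w: int) -> np.ndarray:
    """Eigenvalues of the 2D Dirichlet Laplacian on an h x w grid.

    ``tau_ab = 4 sin^2(a pi / (2(h+1))) + 4 sin^2(b pi / (2(w+1)))`` for
    ``a = 1..h``, ``b = 1..w``; all strictly positive and below 8.
    """
    a = np.arange(1, h + 1)
    b = np.arange(1, w + 1)
    ea = 4.0 * np.sin(a * np.pi / (2 * (h + 1))) ** 2
    eb = 4.0 * np.sin(b * np.pi / (2 * (w + 1))) ** 2
    return ea[:, None] + eb[None, :]


def prox_coil(s: np.ndarray, mu: float) -> np.ndarray:
    """Smoothing map ``mu (D^T D + mu I)^{-1}`` applied per coil and part.

    Implemented spectrally with the orthonormal DST-I; non-expansive, and
    never increases ``gamma``.
    """
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    s = np.asarray(s, dtype=complex)
    squeeze = s.ndim == 2
    if squeeze:
        s = s[None]
    h, w = s.shape[-2:]
    tau = laplacian_eigs(h, w)
    out = np.empty_like(s)
    for i, coil in enumerate(s):
        parts = []
        for part in (coil.real, coil.imag):
            spec = dstn(mu * part, type=1, norm="ortho")
            parts.append(idstn(spec / (tau + mu), type=1, norm="ortho"))
        out[i] = parts[0] + 1j * parts[1]
    return out[0] if squeeze else out
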