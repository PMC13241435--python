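"""Time conditioning: how each expert's variance evolves with diffusion time.

Under the variance-exploding diffusion ``dX_t = sqrt(2) dW_t`` the marginal at
time ``t`` is the data density convolved with ``N(0, 2t I)``.  For ideal
(flat-spectrum, disjoint-support) filters this convolution is implemented
exactly by inflating each expert's variance as
``sigma_k^2(t) = sigma_0^2 + nu_k^2 * 2t`` where ``nu_k`` is the filter's
spectral magnitude.  For practical filters this is a heuristic, and two
learned alternatives are provided: a small MLP time embedding and a
three-parameter-per-filter parametric form.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SpectralTC", "MLPTC", "ParametricTC", "softplus", "elu"]


def softplus(x):
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def elu(x):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _check_t(t: float) -> float:
    t = float(t)
    if t < 0:
        raise ValueError(f"diffusion time must be nonnegative, got {t}")
    return t


class SpectralTC:
    """Theory-derived conditioning: ``sigma_k^2(t) = sigma0^2 + nu_k^2 2t``."""

    variant = "spectral"

    def __init__(self, nu_sq: np.ndarray, sigma0_sq: float):
        self.nu_sq = np.atleast_1d(np.asarray(nu_sq, dtype=float))
        self.sigma0_sq = float(sigma0_sq)

    @property
    def o(self) -> int:
        return self.nu_sq.size

    def sigma_sq(self, t: float) -> np.ndarray:
        t = _check_t(t)
        return self.sigma0_sq + self.nu_sq * 2.0 * t

    @property
    def n_params(self) -> int:
        return 0  # nu^2 is derived from the filters, not learned


class MLPTC:
    """Learned conditioning ``sigma_k^2(t) = sigma0^2 + tau(t)_k``.

    ``tau`` is a three-layer MLP applied to ``sqrt(2t)``:
    ``softplus(L3(elu(L2(elu(L1(.))))))`` with hidden widths (64, 64) and an
    ``o``-dimensional output.  The softplus keeps every output nonnegative so
    the variance never drops below ``sigma0^2``.
    """

    variant = "mlp"

    def __init__(self, o: int, sigma0_sq: float, hidden: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.sigma0_sq = float(sigma0_sq)
        self._o = int(o)
        self.W1 = rng.normal(0, 1.0, size=(hidden, 1))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0, 1.0 / np.sqrt(hidden), size=(hidden, hidden))
        self.b2 = np.zeros(hidden)
        self.W3 = rng.normal(0, 1.0 / np.sqrt(hidden), size=(o, hidden))
        self.b3 = np.zeros(o)

    @property
    def o(self) -> int:
        return self._o

    def tau(self, t: float) -> np.ndarray:
        x = np.array([np.sqrt(2.0 * _check_t(t))])
        h = elu(self.W1 @ x + self.b1)
        h = elu(self.W2 @ h + self.b2)
        return softplus(self.W3 @ h + self.b3)

    def sigma_sq(self, t: float) -> np.ndarray:
        return self.sigma0_sq + self.tau(t)

    @property
    def n_params(self) -> int:
        return sum(a.size for a in (self.W1, self.b1, self.W2, self.b2,
                                    self.W3, self.b3))


class ParametricTC:
    """Parametric conditioning: ``sigma0^2 + th1_k softplus(th2_k sqrt(2t) + th3_k)``.

    Three learnable scalars per filter with ``th1_k > 0`` enforced by clipping.
    """

    variant = "parametric"

    def __init__(self, theta1: np.ndarray, theta2: np.ndarray,
                 theta3: np.ndarray, sigma0_sq: float):
        self.theta1 = np.atleast_1d(np.asarray(theta1, dtype=float))
        self.theta2 = np.atleast_1d(np.asarray(theta2, dtype=float))
        self.theta3 = np.atleast_1d(np.asarray(theta3, dtype=float))
        if np.any(self.theta1 <= 0):
            raise ValueError("theta1 must be strictly positive")
        self.sigma0_sq = float(sigma0_sq)

    @property
    def o(self) -> int:
        return self.theta1.size

    def sigma_sq(self, t: float) -> np.ndarray:
        s = np.sqrt(2.0 * _check_t(t))
        return self.sigma0_sq + self.theta1 * softplus(self.theta2 * s + self.theta3)

    @property
    def n_params(self) -> int:
        return 3 * self.o
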