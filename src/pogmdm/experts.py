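"""One-dimensional Gaussian-mixture experts.

Each expert is a 1D Gaussian mixture with a shared, equally spaced grid of
means on ``[v_min, v_max]``, a shared base variance
``sigma0_sq = (v_max - v_min) / (L - 1)`` and a per-expert weight vector
constrained to the symmetric unit simplex (``w_i = w_{L+1-i}``).  Experts may
share weight vectors through a ``sharing_map`` that assigns each of the ``o``
factors to a weight group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixtureExperts",
    "eval_factor",
    "project_weights",
    "project_simplex",
]


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex.

    Uses the sort-based algorithm of Held, Wolfe & Crowder; O(L log L).
    """
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    idx = np.arange(1, v.size + 1)
    cond = u - css / idx > 0
    rho = idx[cond][-1]
    theta = css[cond][-1] / rho
    return np.maximum(v - theta, 0.0)


def project_weights(w: np.ndarray) -> np.ndarray:
    """Map an arbitrary real vector to a symmetric simplex weight vector.

    Symmetrizes by averaging mirrored pairs, then projects onto the unit
    simplex.  The simplex projection preserves the mirror symmetry, so the
    composite is itself symmetric, and the map is idempotent.
    """
    w = np.asarray(w, dtype=float)
    sym = 0.5 * (w + w[::-1])
    return project_simplex(sym)


def eval_factor(x, w: np.ndarray, means: np.ndarray, sigma_sq: float) -> np.ndarray:
    """Evaluate the mixture density ``sum_i w_i N(x; mu_i, sigma_sq)``."""
    if sigma_sq <= 0:
        raise ValueError(f"sigma_sq must be positive, got {sigma_sq}")
    x = np.asarray(x, dtype=float)
    z = x[..., None] - means
    g = np.exp(-0.5 * z * z / sigma_sq) / np.sqrt(2.0 * np.pi * sigma_sq)
    return g @ np.asarray(w, dtype=float)


def _log_gauss(x: np.ndarray, means: np.ndarray, sigma_sq: float) -> np.ndarray:
    z = x[..., None] - means
    return -0.5 * z * z / sigma_sq - 0.5 * np.log(2.0 * np.pi * sigma_sq)


@dataclass
class MixtureExperts:
    """Collection of ``o`` mixture experts with optional weight sharing.

    Parameters
    ----------
    weights:
        Array of shape ``(n_groups, L)``; row ``g`` is the weight vector of
        sharing group ``g``.
    v_min, v_max:
        End points of the shared grid of means.
    sharing_map:
        Integer array of length ``o`` mapping factor index -> group index.
        The identity map (``n_groups == o``) means no sharing.
    """

    weights: np.ndarray
    v_min: float = -0.5
    v_max: float = 0.5
    sharing_map: np.ndarray | None = None
    means: np.ndarray = field(init=False)
    sigma0_sq: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        L = self.weights.shape[1]
        if L < 2:
            # degenerate single-component grid: put the mean at the center
            self.means = np.array([0.5 * (self.v_min + self.v_max)])
            self.sigma0_sq = float(self.v_max - self.v_min) or 1.0
        else:
            self.means = np.linspace(self.v_min, self.v_max, L)
            self.sigma0_sq = (self.v_max - self.v_min) / (L - 1)
        if self.sharing_map is None:
            self.sharing_map = np.arange(self.weights.shape[0])
        else:
            self.sharing_map = np.asarray(self.sharing_map, dtype=int)

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_groups(self) -> int:
        return self.weights.shape[0]

    @property
    def n_factors(self) -> int:
        return self.sharing_map.size

    @classmethod
    def uniform(cls, o: int, L: int, v_min: float = -0.5, v_max: float = 0.5,
                sharing_map: np.ndarray | None = None) -> "MixtureExperts":
        n_groups = o if sharing_map is None else int(np.max(sharing_map)) + 1
        w = np.full((n_groups, L), 1.0 / L)
        return cls(w, v_min=v_min, v_max=v_max, sharing_map=sharing_map)

    def weights_of(self, k: int) -> np.ndarray:
        """Weight vector of factor ``k`` (resolving the sharing map)."""
        return self.weights[self.sharing_map[k]]

    def project(self) -> None:
        """Project every weight group onto the symmetric simplex, in place."""
        for g in range(self.n_groups):
            self.weights[g] = project_weights(self.weights[g])

    # --- pointwise quantities used by the model -------------------------

    def log_density(self, k: int, x: np.ndarray, sigma_sq: float) -> np.ndarray:
        """``log psi_k(x)`` evaluated elementwise, numerically stable."""
        w = self.weights_of(k)
        a = _log_gauss(np.asarray(x, dtype=float), self.means, sigma_sq)
        with np.errstate(divide="ignore"):
            a = a + np.log(w)
        m = np.max(a, axis=-1, keepdims=True)
        return (m + np.log(np.sum(np.exp(a - m), axis=-1, keepdims=True)))[..., 0]

    def score_1d(self, k: int, x: np.ndarray, sigma_sq: float) -> np.ndarray:
        """``(log psi_k)'(x)``: derivative of the log mixture density."""
        x = np.asarray(x, dtype=float)
        w = self.weights_of(k)
        a = _log_gauss(x, self.means, sigma_sq)
        with np.errstate(divide="ignore"):
            a = a + np.log(w)
        m = np.max(a, axis=-1, keepdims=True)
        r = np.exp(a - m)
        r /= np.sum(r, axis=-1, keepdims=True)
        post_mean = r @ self.means
        return (post_mean - x) / sigma_sq

    def responsibility_terms(self, k: int, x: np.ndarray, sigma_sq: float):
        """Return ``phi_i(x)/psi(x)`` and ``(log psi)'(x)``.

        ``phi_i`` is the *unweighted* Gaussian component; these terms drive the
        analytic weight gradient of the denoising score-matching loss.
        """
        x = np.asarray(x, dtype=float)
        w = self.weights_of(k)
        lg = _log_gauss(x, self.means, sigma_sq)
        with np.errstate(divide="ignore"):
            a = lg + np.log(w)
        m = np.max(a, axis=-1, keepdims=True)
        log_psi = m[..., 0] + np.log(np.sum(np.exp(a - m), axis=-1))
        c = np.exp(lg - log_psi[..., None])  # phi_i / psi
        r = np.exp(a - log_psi[..., None])   # w_i phi_i / psi
        g = (r @ self.means - x) / sigma_sq
        return c, g
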