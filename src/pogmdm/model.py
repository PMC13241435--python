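"""The product-of-Gaussian-mixture diffusion model (PoGMDM).

The time-dependent image density is the product of experts

    p(x, t)  propto  prod_l prod_k  psi_k((K_k x)_l, w_k, t),

where ``K_k`` are circular convolutions and ``psi_k`` is a 1D Gaussian
mixture whose variance evolves with diffusion time through the attached
time-conditioning module.  Because the density is explicit, the score
``grad log p`` is available in closed form and is an exact conservative
vector field.
"""

from __future__ import annotations

import numpy as np

from .bank import FilterBank
from .experts import MixtureExperts
from .timecond import MLPTC, ParametricTC, SpectralTC

__all__ = ["PoGMDMModel", "log_prior", "score", "denoise_tweedie",
           "count_parameters"]


class PoGMDMModel:
    """Filter bank + mixture experts + time conditioning."""

    def __init__(self, bank: FilterBank, experts: MixtureExperts, tc):
        if bank.o != experts.n_factors:
            raise ValueError(
                f"bank has {bank.o} filters, experts map {experts.n_factors}")
        if tc.o != bank.o:
            raise ValueError(
                f"time conditioning is {tc.o}-dimensional, bank has {bank.o}")
        self.bank = bank
        self.experts = experts
        self.tc = tc
        self.ema_shadow: np.ndarray | None = None

    # -- construction helpers ------------------------------------------

    @classmethod
    def flf(cls, grid_shape, o: int = 20, r: int = 5, L: int = 125,
            v_min: float = -1.0, v_max: float = 1.0,
            tc_variant: str = "spectral", rng=None) -> "PoGMDMModel":
        """The fully-learned-filter configuration (o zero-mean r x r kernels)."""
        rng = rng or np.random.default_rng(0)
        bank = FilterBank.random_learnable(o, r, grid_shape, rng)
        experts = MixtureExperts.uniform(o, L, v_min=v_min, v_max=v_max)
        sigma0 = experts.sigma0_sq
        if tc_variant == "spectral":
            tc = SpectralTC(bank.nu_sq(), sigma0)
        elif tc_variant == "mlp":
            tc = MLPTC(o, sigma0, rng=rng)
        elif tc_variant == "parametric":
            tc = ParametricTC(np.ones(o), np.ones(o), np.zeros(o), sigma0)
        else:
            raise ValueError(f"unknown tc variant {tc_variant!r}")
        return cls(bank, experts, tc)

    def sigma_sq_at(self, k: int, t: float) -> float:
        """Variance of factor ``k`` at diffusion time ``t``."""
        return float(self.tc.sigma_sq(t)[k])

    def refresh_spectral_tc(self) -> None:
        """Recompute nu^2 from the (possibly updated) filters."""
        if isinstance(self.tc, SpectralTC):
            self.tc.nu_sq = self.bank.nu_sq()

    def project(self) -> None:
        """Enforce all parameter constraints in place."""
        self.bank.project()
        self.experts.project()
        self.refresh_spectral_tc()

    # -- density, score, denoiser --------------------------------------

    def log_prior(self, x: np.ndarray, t: float) -> float:
        """Energy ``-sum_l sum_k log psi_k((K_k x)_l, t)``.

        This is the negative log of the unnormalized density; lower energy
        means more probable under the prior.
        """
        z = self.bank.apply(np.asarray(x, dtype=float))
        sig = self.tc.sigma_sq(t)
        total = 0.0
        for k in range(self.bank.o):
            total -= float(np.sum(self.experts.log_density(k, z[k], sig[k])))
        return total

    def score(self, x: np.ndarray, t: float) -> np.ndarray:
        """Closed-form ``grad log p(x, t)``: sum_k K_k^T (log psi_k)'(K_k x)."""
        x = np.asarray(x, dtype=float)
        z = self.bank.apply(x)
        sig = self.tc.sigma_sq(t)
        g = np.empty_like(z)
        for k in range(self.bank.o):
            g[k] = self.experts.score_1d(k, z[k], sig[k])
        return self.bank.apply_adjoint(g)

    def score_stack(self, xs: np.ndarray, t: float) -> np.ndarray:
        """Score of a stack of images ``(..., h, w)`` (channels batched)."""
        flat = xs.reshape(-1, *self.bank.grid_shape)
        return np.stack([self.score(im, t) for im in flat]).reshape(xs.shape)

    def denoise_tweedie(self, x: np.ndarray, t: float) -> np.ndarray:
        """One-step empirical-Bayes denoiser: ``x + 2t grad log p(x, t)``."""
        return np.asarray(x, dtype=float) + 2.0 * t * self.score(x, t)

    # -- parameter bookkeeping -----------------------------------------

    def count_parameters(self) -> int:
        """Number of learnable values the model stores.

        Filters contribute their raw parameter count (constraint projections
        do not reduce it), each distinct weight group contributes only its
        ``ceil(L/2)`` free values because symmetry mirrors the rest, and the
        time conditioning contributes its own parameters.
        """
        L = self.experts.n_components
        n_weights = self.experts.n_groups * ((L + 1) // 2)
        return self.bank.n_filter_params + n_weights + self.tc.n_params

    # -- flat parameter vector (EMA / checkpoint) ----------------------

    def get_weights_flat(self) -> np.ndarray:
        return self.experts.weights.ravel().copy()

    def set_weights_flat(self, v: np.ndarray) -> None:
        self.experts.weights = np.asarray(v, dtype=float).reshape(
            self.experts.weights.shape).copy()

    def ema_update(self, momentum: float = 0.999) -> None:
        """shadow <- momentum * shadow + (1 - momentum) * current weights."""
        cur = self.get_weights_flat()
        if self.ema_shadow is None:
            self.ema_shadow = cur
        else:
            self.ema_shadow = momentum * self.ema_shadow + (1 - momentum) * cur

    # -- checkpointing --------------------------------------------------

    def save(self, path) -> None:
        data = {
            "schema": np.array(1),
            "weights": self.experts.weights,
            "sharing_map": self.experts.sharing_map,
            "v_min": np.array(self.experts.v_min),
            "v_max": np.array(self.experts.v_max),
            "grid_shape": np.array(self.bank.grid_shape),
            "zero_mean": np.array(self.bank.zero_mean),
            "tc_variant": np.array(self.tc.variant),
        }
        if self.bank.kernels is not None:
            for i, k in enumerate(self.bank.kernels):
                data[f"kernel_{i}"] = k
            data["n_kernels"] = np.array(len(self.bank.kernels))
        else:
            data["spectra"] = self.bank.spectral_magnitude
        if isinstance(self.tc, SpectralTC):
            data["nu_sq"] = self.tc.nu_sq
        elif isinstance(self.tc, ParametricTC):
            data["theta1"] = self.tc.theta1
            data["theta2"] = self.tc.theta2
            data["theta3"] = self.tc.theta3
        elif isinstance(self.tc, MLPTC):
            for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
                data[f"mlp_{name}"] = getattr(self.tc, name)
        if self.ema_shadow is not None:
            data["ema_shadow"] = self.ema_shadow
        np.savez(path, **data)

    @classmethod
    def load(cls, path) -> "PoGMDMModel":
        with np.load(path, allow_pickle=False) as z:
            grid = tuple(int(n) for n in z["grid_shape"])
            if "n_kernels" in z:
                kernels = [z[f"kernel_{i}"] for i in range(int(z["n_kernels"]))]
                bank = FilterBank(kernels=kernels, grid_shape=grid,
                                  zero_mean=bool(z["zero_mean"]))
            else:
                bank = FilterBank(spectra=z["spectra"], grid_shape=grid,
                                  learnable=False)
            experts = MixtureExperts(z["weights"], v_min=float(z["v_min"]),
                                     v_max=float(z["v_max"]),
                                     sharing_map=z["sharing_map"])
            variant = str(z["tc_variant"])
            s0 = experts.sigma0_sq
            if variant == "spectral":
                tc = SpectralTC(z["nu_sq"], s0)
            elif variant == "parametric":
                tc = ParametricTC(z["theta1"], z["theta2"], z["theta3"], s0)
            else:
                tc = MLPTC(bank.o, s0)
                for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
                    setattr(tc, name, z[f"mlp_{name}"])
            model = cls(bank, experts, tc)
            if "ema_shadow" in z:
                model.ema_shadow = z["ema_shadow"]
        return model


# Functional aliases matching the operation-level surface.

def log_prior(image, t, model: PoGMDMModel) -> float:
    return model.log_prior(image, t)


def score(image, t, model: PoGMDMModel) -> np.ndarray:
    return model.score(image, t)


def denoise_tweedie(image, t, model: PoGMDMModel) -> np.ndarray:
    return model.denoise_tweedie(image, t)


def count_parameters(model: PoGMDMModel) -> int:
    return model.count_parameters()
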