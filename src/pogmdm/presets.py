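"""Ready-made model configurations.

``reference_configurations`` builds the five model variants whose learnable
parameter totals serve as bookkeeping cross-checks, and
``desk_prior`` assembles and quickly fits a small convolutional prior used
by the desk-scale reconstruction experiments and examples.
"""

from __future__ import annotations

import numpy as np

from .bank import FilterBank
from .experts import MixtureExperts, project_weights
from .model import PoGMDMModel
from .phantoms import PhantomSpec, make_phantom
from .shearlets import ShearletConfig, build_shearlet_bank, sharing_map_for
from .timecond import MLPTC, ParametricTC, SpectralTC
from .training import TrainConfig, normalize_image, train

__all__ = ["reference_configurations", "desk_prior", "dsm_prior",
           "difference_bank"]


def reference_configurations(grid_shape=(64, 64)) -> dict[str, PoGMDMModel]:
    """The five reference model configurations, for parameter bookkeeping.

    - ``flf``: 20 fully learned 5x5 filters, L=125 mixtures, spectral tc;
    - ``flf_mlp_tc``: same filters with the learned MLP time conditioning;
    - ``flf_parametric_tc``: same with the 3-parameter-per-filter form;
    - ``shearlet``: two-scale shearlet bank (h1 of length 9, P 17x17);
    - ``shearlet_shared_both``: shearlet bank with potentials shared within
      and across cones (three potentials per scale).
    """
    out = {}
    out["flf"] = PoGMDMModel.flf(grid_shape, tc_variant="spectral",
                                 rng=np.random.default_rng(0))
    out["flf_mlp_tc"] = PoGMDMModel.flf(grid_shape, tc_variant="mlp",
                                        rng=np.random.default_rng(0))
    out["flf_parametric_tc"] = PoGMDMModel.flf(
        grid_shape, tc_variant="parametric", rng=np.random.default_rng(0))

    cfg = ShearletConfig(scales=2, grid_shape=tuple(grid_shape))
    for name, strategy in (("shearlet", "none"),
                           ("shearlet_shared_both", "both")):
        bank = build_shearlet_bank(cfg)
        smap = sharing_map_for(cfg.labels, strategy)
        experts = MixtureExperts.uniform(bank.o, 125, v_min=-0.5, v_max=0.5,
                                         sharing_map=smap)
        tc = SpectralTC(bank.nu_sq(), experts.sigma0_sq)
        out[name] = PoGMDMModel(bank, experts, tc)
    return out


def difference_bank(grid_shape) -> FilterBank:
    """Four fixed first/second difference filters (desk-scale prior)."""
    kernels = [
        np.array([[1.0, -1.0]]),
        np.array([[1.0], [-1.0]]),
        np.array([[1.0, -2.0, 1.0]]) / 2.0,
        np.array([[1.0], [-2.0], [1.0]]) / 2.0,
    ]
    return FilterBank(kernels=kernels, grid_shape=grid_shape, zero_mean=True,
                      learnable=False)


def _em_weights(samples: np.ndarray, means: np.ndarray, sigma_sq: float,
                iters: int = 40) -> np.ndarray:
    """Maximum-likelihood mixture weights for fixed means and variance (EM)."""
    w = np.full(means.size, 1.0 / means.size)
    log_g = -0.5 * (samples[:, None] - means) ** 2 / sigma_sq
    for _ in range(iters):
        a = log_g + np.log(w + 1e-300)
        a -= a.max(axis=1, keepdims=True)
        r = np.exp(a)
        r /= r.sum(axis=1, keepdims=True)
        w = r.mean(axis=0)
    return w


def desk_prior(grid_shape=(64, 64), L: int = 125, n_train_images: int = 16,
               seed: int = 0, subsample: int = 7) -> PoGMDMModel:
    """Small convolutional prior fitted on synthetic phantoms.

    Fixed unit-gain difference filters with the spectral (theory-derived)
    time conditioning; the mixture weights of each factor are the
    maximum-likelihood (EM) fit of that filter's response marginal over a
    batch of phantoms, projected onto the symmetric simplex.  Fitting the
    clean-image factors and letting the variance adaptation supply the
    time dependence keeps the score well calibrated at the small noise
    levels where reconstruction quality is decided; the fit takes a few
    seconds on one CPU.
    """
    bank = difference_bank(grid_shape)
    experts = MixtureExperts.uniform(bank.o, L, v_min=-0.5, v_max=0.5)
    rng = np.random.default_rng(seed)
    responses = [[] for _ in range(bank.o)]
    for _ in range(n_train_images):
        spec = PhantomSpec(shape=tuple(grid_shape),
                           seed=int(rng.integers(2 ** 31)))
        z = bank.apply(normalize_image(make_phantom(spec)))
        for k in range(bank.o):
            responses[k].append(z[k].ravel())
    weights = np.stack([
        project_weights(_em_weights(np.concatenate(responses[k])[::subsample],
                                    experts.means, experts.sigma0_sq))
        for k in range(bank.o)])
    experts = MixtureExperts(weights, v_min=-0.5, v_max=0.5)
    tc = SpectralTC(bank.nu_sq(), experts.sigma0_sq)
    return PoGMDMModel(bank, experts, tc)


def dsm_prior(grid_shape=(64, 64), L: int = 125, iterations: int = 300,
              horizon: float = 1.0, seed: int = 0) -> PoGMDMModel:
    """Difference-filter prior with weights trained by DSM on phantoms."""
    bank = difference_bank(grid_shape)
    experts = MixtureExperts.uniform(bank.o, L, v_min=-0.5, v_max=0.5)
    tc = SpectralTC(bank.nu_sq(), experts.sigma0_sq)
    model = PoGMDMModel(bank, experts, tc)

    def source(rng: np.random.Generator) -> np.ndarray:
        spec = PhantomSpec(shape=tuple(grid_shape),
                           seed=int(rng.integers(2 ** 31)))
        return normalize_image(make_phantom(spec))

    cfg = TrainConfig(iterations=iterations, batch_size=2, seed=seed,
                      learning_rate=0.05, horizon=horizon,
                      log_every=max(1, iterations // 5))
    model, _ = train(model, source, cfg)
    return model
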