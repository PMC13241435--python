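"""Denoising score matching for the product-of-Gaussian-mixture prior.

The objective is the ancestral-sampling form of denoising score matching,

    E_{x0, t, z} || x0 - x_t - 2t grad log p(x_t, t) ||^2 ,
    x_t = x0 + sqrt(2t) z,   t ~ U(0, T),

minimized over the mixture weights with an adaptive-moment optimizer.  The
weight gradient is analytic: with unweighted component responsibilities
``c_i = phi_i / psi`` and 1D score ``g = (log psi)'``,

    d g / d w_i = c_i ((mu_i - z) / sigma^2 - g),

so the loss gradient is an inner product of the back-projected residual with
these fields.  Every step is followed by projection onto the constraint set
(symmetric simplex weights, zero-mean filters) and an exponential moving
average of the weights is maintained; the EMA weights are returned.

Filters and time-conditioning parameters are held fixed during training;
the trainable surface of this implementation is the mixture weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PoGMDMModel

__all__ = ["TrainConfig", "sample_noisy", "dsm_loss", "train",
           "normalize_image", "weight_gradients"]


def normalize_image(x: np.ndarray) -> np.ndarray:
    """Scale by the maximum magnitude so that ``max |x| = 1``."""
    x = np.asarray(x, dtype=float)
    m = np.max(np.abs(x))
    if m == 0:
        raise ValueError("cannot normalize an all-zero image")
    return x / m


def sample_noisy(x0: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Ancestral sample ``x_t = x0 + sqrt(2t) z`` with ``z ~ N(0, I)``."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    x0 = np.asarray(x0, dtype=float)
    return x0 + np.sqrt(2.0 * t) * rng.standard_normal(x0.shape)


def dsm_loss(batch, model: PoGMDMModel) -> float:
    """Mean over the batch of ``||x0 - x_t - 2t score(x_t, t)||^2``."""
    total = 0.0
    for x0, xt, t in batch:
        if t <= 0:
            raise ValueError("denoising score matching requires t > 0")
        r = x0 - xt - 2.0 * t * model.score(xt, t)
        total += float(np.sum(r * r))
    return total / len(batch)


def weight_gradients(batch, model: PoGMDMModel) -> np.ndarray:
    """Analytic gradient of the DSM loss w.r.t. every weight group.

    Returns an array of shape ``(n_groups, L)``.
    """
    experts = model.experts
    grads = np.zeros_like(experts.weights)
    for x0, xt, t in batch:
        sig = model.tc.sigma_sq(t)
        z = model.bank.apply(xt)
        g_fields = np.empty_like(z)
        cache = []
        for k in range(model.bank.o):
            c, g = experts.responsibility_terms(k, z[k], sig[k])
            g_fields[k] = g
            cache.append((c, g))
        r = x0 - xt - 2.0 * t * model.bank.apply_adjoint(g_fields)
        kr = model.bank.apply(r)        # K_k r for every filter
        for k in range(model.bank.o):
            c, g = cache[k]
            dg = c * ((experts.means - z[k][..., None]) / sig[k] - g[..., None])
            grads[experts.sharing_map[k]] += \
                -4.0 * t * np.tensordot(kr[k], dg, axes=(range(kr[k].ndim),
                                                         range(kr[k].ndim)))
    return grads / len(batch)


@dataclass
class TrainConfig:
    iterations: int = 2000
    batch_size: int = 4
    horizon: float = 1.0          # T: upper end of the uniform time range
    t_eps: float = 1e-4           # lower bound avoids the 1/(2t) blow-up
    learning_rate: float = 0.02
    ema_momentum: float = 0.999
    seed: int = 0
    log_every: int = 100

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if not 0 <= self.ema_momentum < 1:
            raise ValueError("EMA momentum must lie in [0, 1)")


def train(model: PoGMDMModel, image_source, config: TrainConfig):
    """Run the DSM loop; returns ``(model_with_ema_weights, log)``.

    ``image_source`` is a callable ``rng -> image`` yielding normalized
    training images.  The log is a list of ``(iteration, loss)`` rows.
    """
    rng = np.random.default_rng(config.seed)
    w = model.get_weights_flat()
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    shadow = w.copy()
    log = []
    b1, b2, eps = 0.9, 0.999, 1e-8
    for it in range(1, config.iterations + 1):
        batch = []
        for _ in range(config.batch_size):
            x0 = image_source(rng)
            t = rng.uniform(config.t_eps, config.horizon)
            batch.append((x0, sample_noisy(x0, t, rng), t))
        g = weight_gradients(batch, model).ravel()
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient at iteration {it}")
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mh = m / (1 - b1 ** it)
        vh = v / (1 - b2 ** it)
        w = w - config.learning_rate * mh / (np.sqrt(vh) + eps)
        model.set_weights_flat(w)
        model.project()
        w = model.get_weights_flat()
        shadow = config.ema_momentum * shadow + (1 - config.ema_momentum) * w
        if it % config.log_every == 0 or it == 1:
            loss = dsm_loss(batch, model)
            if not np.isfinite(loss):
                raise FloatingPointError(f"divergent loss at iteration {it}")
            log.append((it, loss))
    model.set_weights_flat(shadow)
    model.project()
    model.ema_shadow = model.get_weights_flat()
    return model, log
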