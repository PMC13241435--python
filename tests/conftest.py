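import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model():
    """Tiny convolutional model: 2 random 3x3 zero-mean filters, L=9."""
    import pogmdm as pg

    r = np.random.default_rng(7)
    bank = pg.FilterBank.random_learnable(2, 3, (6, 6), r)
    experts = pg.MixtureExperts.uniform(2, 9, v_min=-0.5, v_max=0.5)
    tc = pg.SpectralTC(bank.nu_sq(), experts.sigma0_sq)
    m = pg.PoGMDMModel(bank, experts, tc)
    # non-uniform symmetric weights so score tests are non-trivial
    w = np.exp(-0.5 * (np.linspace(-2, 2, 9)) ** 2) + 0.05
    w = w / w.sum()
    m.experts.weights = np.stack([w, w[::-1]])
    m.experts.project()
    return m


def dense_dirichlet_D(n: int) -> np.ndarray:
    """Forward differences with zeros outside: (n+1) x n matrix."""
    D = np.zeros((n + 1, n))
    D[0, 0] = 1.0
    for i in range(1, n):
        D[i, i] = 1.0
        D[i, i - 1] = -1.0
    D[n, n - 1] = -1.0
    return D


def dense_dirichlet_laplacian(h: int, w: int) -> np.ndarray:
    Dh = dense_dirichlet_D(h)
    Dw = dense_dirichlet_D(w)
    D2 = np.vstack([np.kron(Dh, np.eye(w)), np.kron(np.eye(h), Dw)])
    return D2.T @ D2
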