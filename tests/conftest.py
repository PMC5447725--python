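import numpy as np
import pytest

import gscata as g


@pytest.fixture(scope="session")
def one_factor_spec():
    return g.parse_model("F =~ x1 + x2 + x3 + x4\n")


@pytest.fixture(scope="session")
def one_factor_sigma():
    lam = np.array([0.9, 0.8, 0.7, 0.6])
    Sig = np.outer(lam, lam)
    np.fill_diagonal(Sig, 1.0)
    return Sig


def exact_sample_data(Sigma, n, seed, names=None):
    """Data whose *sample* correlation matrix equals Sigma exactly.

    A raw Gaussian draw is centered, whitened empirically, and recolored by
    the Cholesky factor of Sigma, so Z'Z/N == Sigma to machine precision.
    """
    J = Sigma.shape[0]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, J))
    X -= X.mean(axis=0)
    S = X.T @ X / n
    X = X @ np.linalg.inv(np.linalg.cholesky(S)).T
    Z = X @ np.linalg.cholesky(Sigma).T
    if names is None:
        names = tuple(f"x{j + 1}" for j in range(J))
    return g.StandardizedData(Z=Z, names=names)


@pytest.fixture(scope="session")
def one_factor_exact_data(one_factor_sigma):
    return exact_sample_data(one_factor_sigma, n=200, seed=3)


@pytest.fixture(scope="session")
def one_factor_noisy_data(one_factor_sigma):
    rng = np.random.default_rng(17)
    L = np.linalg.cholesky(one_factor_sigma)
    X = rng.standard_normal((500, 4)) @ L.T
    return g.standardize(X, names=("x1", "x2", "x3", "x4"))


@pytest.fixture(scope="session")
def m0_data():
    cfg = g.builtin_config("M0", n=2000, seed=9)
    return g.standardize(g.generate(cfg, clip=False))


@pytest.fixture(scope="session")
def m0_fit(m0_data):
    return g.fit_gsca(m0_data, g.builtin_model("M0"))


@pytest.fixture(scope="session")
def m3_data():
    cfg = g.builtin_config("M3", n=2000, seed=23)
    return g.standardize(g.generate(cfg, clip=False))
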