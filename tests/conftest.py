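import numpy as np
import pytest

import countfactor as cf


@pytest.fixture(scope="session")
def small_sim():
    """Moderate-signal bilinear simulation reused across modules."""
    Y, truth = cf.simulate_gbm(I=60, J=150, M=2, kappa=3.0, rng=11)
    return Y, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    Y, _ = small_sim
    return cf.fit_gbm(Y, M=2, seed=0, max_iter=400)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def positive_count_instance(rng, I, J, M=1, sigma_scale=0.6, depth=8.0):
    """Tiny model-generated counts, resampled until strictly positive.

    Strictly positive counts guarantee the Poisson bilinear MLE exists,
    which tiny matrices with zeros do not (the likelihood can increase
    without bound along directions sending some means to zero).
    """
    for _ in range(200):
        U = cf.sample_stiefel(I, M, rng)
        V = cf.sample_stiefel(J, M, rng)
        sigma = np.full(M, sigma_scale)
        alpha = np.log(depth) / 2 + 0.2 * rng.standard_normal(I)
        beta = np.log(depth) / 2 + 0.2 * rng.standard_normal(J)
        mu = np.exp(alpha[:, None] + beta[None, :] + (U * sigma) @ V.T)
        Y = rng.poisson(mu)
        if Y.min() >= 1:
            return Y
    raise RuntimeError("failed to draw a strictly positive count matrix")
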