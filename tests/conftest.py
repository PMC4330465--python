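import numpy as np
import pytest

from smdqsar.datasets import load_ache_training_set


@pytest.fixture(scope="session")
def training_set():
    """The packaged 18-compound AChE training table."""
    return load_ache_training_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


def make_latent_problem(rng, n=24, k=8, n_informative=3, sigma=0.3):
    """Regression problem with known sparse coefficients in scaled space."""
    X = rng.standard_normal((n, k))
    beta = np.zeros(k)
    beta[:n_informative] = rng.choice([-1.0, 1.0], n_informative) * rng.uniform(0.6, 1.2, n_informative)
    y = X @ beta + sigma * rng.standard_normal(n)
    return X, y, beta
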