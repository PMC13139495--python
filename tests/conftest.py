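import numpy as np
import pytest

from songrules.basis import raised_cosine_basis
from songrules.model import HMMGLMParams


@pytest.fixture(scope="session")
def small_basis():
    """A short basis for fast design-building in unit tests."""
    return raised_cosine_basis(n_lags=30, n_basis=4)


def random_params(K: int, P: int, rng: np.random.Generator, scale: float = 0.5) -> HMMGLMParams:
    """A valid random parameter set for oracle tests."""
    W = rng.normal(0, scale, size=(K, 3, P))
    W[:, 2] = 0.0
    pi = rng.dirichlet(np.ones(K))
    alpha = rng.dirichlet(np.ones(K), size=K)
    return HMMGLMParams(pi=pi, alpha=alpha, weights=W)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
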