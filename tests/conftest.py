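import numpy as np
import pytest

from bipsda.gmm import GaussianMixture, PriorSpec, build_prior


@pytest.fixture(scope="session")
def prior():
    """The ten-dimensional three-component benchmark prior."""
    return build_prior(PriorSpec(seed=99))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def mix1d():
    """A well-separated two-component 1-D mixture for quadrature oracles."""
    return GaussianMixture(
        weights=np.array([0.3, 0.7]),
        means=np.array([[-2.0], [1.5]]),
        covariances=np.array([[[0.5]], [[1.2]]]),
    )


@pytest.fixture(scope="session")
def mix2d():
    """A 2-D two-component mixture with correlated covariances."""
    c1 = np.array([[1.0, 0.3], [0.3, 0.8]])
    c2 = np.array([[0.6, -0.2], [-0.2, 1.5]])
    return GaussianMixture(
        weights=np.array([0.45, 0.55]),
        means=np.array([[-1.0, 0.5], [2.0, -1.0]]),
        covariances=np.stack([c1, c2]),
    )
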