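import numpy as np
import pytest

from reinworld import ModelConfig, NicheShape, build_kernel, sample_population


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def gauss_shape():
    return NicheShape("gaussian", 5.0)


@pytest.fixture
def gauss_kernel(gauss_shape):
    return build_kernel(gauss_shape)


@pytest.fixture
def std_config():
    """The standard setting: R = 100, sigma = 5, one environmental variable."""
    return ModelConfig(K=100, n_env=1, seed=7)


@pytest.fixture
def small_pop(std_config, rng):
    return sample_population(std_config, rng)
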