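import numpy as np
import pytest

from ppibench.synthetic import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def dataset(default_config):
    """records, latents, pairs, embeddings for the default study conditions."""
    return make_dataset(default_config)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_proteins=36, pairs_per_protein=6, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return make_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
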