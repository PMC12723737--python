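import numpy as np
import pytest

from phopt.embed import FixtureEmbedder
from phopt.network import ModelConfig, init_state
from phopt.synth import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def embedder8():
    return FixtureEmbedder(dim=8, seed=1)


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(dim=8, n_head=2, n_rd=2, window_sizes=(1, 2, 3), seed=3)


@pytest.fixture(scope="session")
def tiny_state(tiny_config):
    return init_state(tiny_config)


@pytest.fixture(scope="session")
def small_records():
    """60 synthetic labeled records (composition-driven labels)."""
    return generate_dataset(SyntheticSpec(n=60, seed=3,
                                          length_range=(25, 60)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
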