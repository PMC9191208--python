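import numpy as np
import pytest

from pepscore import make_fixture_complex
from pepscore.gnn import ModelConfig, init_params
from pepscore.graph import build_graph


@pytest.fixture(scope="session")
def fixture_complex():
    return make_fixture_complex(seed=0)


@pytest.fixture(scope="session")
def fixture_graph(fixture_complex):
    return build_graph(fixture_complex)


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig(
        edge_dim=6, vertex_dim=5, global_dim=4, head_channels=3,
        dropout_rate=0.0, seed=11,
    )


@pytest.fixture()
def small_params(small_config):
    return init_params(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
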