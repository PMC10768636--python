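import numpy as np
import pytest

from efgraph import synthetic


@pytest.fixture(scope="session")
def fixtures():
    return synthetic.worked_fixtures()


@pytest.fixture()
def triangle(fixtures):
    return fixtures["triangle"]


@pytest.fixture()
def bias_fixture(fixtures):
    return fixtures["bias_fixture"]


@pytest.fixture(scope="session")
def small_sbm():
    return synthetic.stochastic_block_model([50, 50], 0.2, 0.02, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
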