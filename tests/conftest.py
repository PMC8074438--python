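import numpy as np
import pytest

from fluxsens.fixtures import (
    make_linear_chain_model,
    make_min_coupled_model,
    make_random_small_model,
)


@pytest.fixture(scope="session")
def min_coupled():
    return make_min_coupled_model()


@pytest.fixture(scope="session")
def chain_11():
    return make_linear_chain_model((1.0, 1.0))


@pytest.fixture(scope="session")
def chain_single():
    return make_linear_chain_model((1.0,))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def min_coupled_json(tmp_path_factory, min_coupled):
    from fluxsens.model_io import save_model

    path = tmp_path_factory.mktemp("models") / "min_coupled.json"
    save_model(min_coupled, path)
    return str(path)
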