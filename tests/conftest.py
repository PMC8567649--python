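import numpy as np
import pytest

from hedstrat.grantham import build_grantham_matrix
from hedstrat.simulate import SimulationConfig, write_bundle


@pytest.fixture(scope="session")
def integer_matrix():
    return build_grantham_matrix(mode="published-integer")


@pytest.fixture(scope="session")
def continuous_matrix():
    return build_grantham_matrix(mode="continuous")


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """One default-shape synthetic input bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle") / "cohort"
    write_bundle(SimulationConfig(seed=11), out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
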