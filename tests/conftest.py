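import numpy as np
import pytest

from popcode.encoder import PopulationParams
from popcode.error_dist import walk_table_set


@pytest.fixture(scope="session")
def table_set():
    """Default uniform-walk resultant table set (built once per session)."""
    return walk_table_set()


@pytest.fixture(scope="session")
def group_params():
    """Group-mean maximum-likelihood parameters of the population model."""
    return PopulationParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160907)
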