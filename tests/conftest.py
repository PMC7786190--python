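import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sugarshock as ss

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def wt():
    return ss.WT


@pytest.fixture(scope="session")
def full_network(wt):
    return ss.build_network(wt, "FULL")


@pytest.fixture(scope="session")
def wt_ensemble(wt):
    """A 1000-replicate wild-type ensemble shared across tests."""
    return ss.run_ensemble(wt, "FULL", n_replicates=1000, base_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
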