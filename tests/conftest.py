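import numpy as np
import pytest

import rpqcluster as rc


@pytest.fixture(scope="session")
def default_config():
    return rc.make_default_config(n_participants=467, seed=0)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return rc.generate_cohort(default_config, seed=0)


@pytest.fixture(scope="session")
def planted(default_config):
    return rc.planted_partition(default_config)


@pytest.fixture(scope="session")
def large_cohort():
    """One bigger cohort shared by the statistically-hungry tests."""
    cfg = rc.make_default_config(n_participants=5000, seed=7)
    return cfg, rc.generate_cohort(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
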