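import numpy as np
import pytest

from fmca import (PatientProfile, ScoringConfig, default_config,
                  make_test_definition, simulate_trial)


@pytest.fixture(scope="session")
def config() -> ScoringConfig:
    return default_config()


@pytest.fixture(scope="session")
def testdefs(config):
    return {tid: make_test_definition(tid, config) for tid in ("T1", "T2", "T3")}


@pytest.fixture(scope="session")
def clean_trials():
    """Noise-free full-ability trials for each test, shared across tests."""
    return {tid: simulate_trial(PatientProfile(ability=1.0, seed=3), tid)
            for tid in ("T1", "T2", "T3")}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
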