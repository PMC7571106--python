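import numpy as np
import pytest

from wristgait.synthetic_gait import (GaitSimConfig, sample_subject_profiles,
                                      simulate_dataset, simulate_session)


@pytest.fixture(scope="session")
def small_config():
    """Small but fully structured cohort: 3 subjects, 2 trials/condition."""
    return GaitSimConfig(n_subjects=3, trials_per_condition=2,
                         duration_range=(16.0, 20.0), rng_seed=1234)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def one_session(small_config):
    profile = sample_subject_profiles(1, seed=5)[0]
    return simulate_session(profile, "normal", "right", 0, small_config, seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(20200918)
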