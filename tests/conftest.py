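import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from tactoj import (
    CohortConfig,
    GroupConfig,
    Observer,
    build_trial_schedule,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def schedule():
    return build_trial_schedule(start_posture="uncrossed", seed=1)


@pytest.fixture(scope="session")
def simulated_subject(schedule):
    """One left-affected observer run through the standard schedule."""
    obs = Observer(pss_true=30.0, sigma=100.0, crossed_sigma_factor=2.0, affected_side="left")
    return obs, simulate_subject(obs, schedule, rng_seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject cohort (2 per group), cheap enough for I/O and CLI tests."""
    config = CohortConfig(
        groups={
            "CRPS": GroupConfig(n=2, pain_duration_mean=10.0, n_missing_temp=1),
            "shoulder": GroupConfig(n=2, pain_duration_mean=24.0),
            "wrist": GroupConfig(n=2, pain_duration_mean=24.0),
        },
        seed=3,
    )
    meta, trials, truth = simulate_cohort(config)
    return meta, trials, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
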