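import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrvscreen import (
    CohortConfig,
    StateProfile,
    SubjectParams,
    extract_features,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def stationary_params(
    mean_rr=800.0, lf_amp=20.0, hf_amp=30.0, resp_freq=0.25, noise_sd=5.0
) -> SubjectParams:
    """A subject with no state reactivity at all."""
    return SubjectParams(
        mean_rr=StateProfile(mean_rr, mean_rr, mean_rr),
        lf_amp=StateProfile(lf_amp, lf_amp, lf_amp),
        hf_amp=StateProfile(hf_amp, hf_amp, hf_amp),
        resp_freq=resp_freq,
        noise_sd=noise_sd,
        blunting=0.0,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded paper-sized cohort with extracted features (shared: slow)."""
    subjects = simulate_cohort(CohortConfig(seed=1))
    X = np.array([extract_features(s.rr).as_array() for s in subjects])
    y = np.array([1 if s.diagnosis == "MDD" else 0 for s in subjects])
    sds = np.array([s.sds for s in subjects])
    return subjects, X, y, sds
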