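import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cvrpipe import SynthParams, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def clean_params():
    """Noise- and artifact-free generator settings for recovery tests."""
    return SynthParams(n_low=3, n_high=2, noise_sd=0.0, n_bouts=1, seed=11)


@pytest.fixture(scope="session")
def clean_cohort(clean_params):
    return simulate_cohort(clean_params)


@pytest.fixture(scope="session")
def clean_recording(clean_params, clean_cohort):
    profile, truth = clean_cohort[0]
    return simulate_recording(profile, truth, clean_params, 0)


@pytest.fixture(scope="session")
def fast_params():
    """Reduced sampling for pipeline-level tests."""
    return SynthParams(n_low=3, n_high=2, sample_rate=125.0, duration=300.0,
                       n_bouts=1, seed=3)
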