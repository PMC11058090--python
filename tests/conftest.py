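import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def noiseless_spec():
    from syngait import SynergySpec

    return SynergySpec(noise_sd=0.0, seed=7)


@pytest.fixture
def noiseless_trial(noiseless_spec):
    from syngait import synthesize_trial

    return synthesize_trial(noiseless_spec)
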