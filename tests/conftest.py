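import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight short synthetic sows for fast dataset/model tests."""
    from farrowcast.synth import SimConfig, generate_cohort

    cfg = SimConfig(n_sows=8, horizon_points=432, ramp_start=144,
                    sigmoid_midpoint=52.0, diurnal_period=288, seed=7)
    return generate_cohort(cfg)
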