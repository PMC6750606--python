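import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_cohort():
    """312-patient synthetic cohort with the default generator settings."""
    from omega3cmr.simulate import CohortConfig, generate_cohort

    df, truth = generate_cohort(CohortConfig(seed=7))
    return df, truth
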