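import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def dorset_model_cohort():
    """Dorset-sized cohort with outcomes drawn from the score itself."""
    from idiomval import OutcomeMode, cohort_preset, generate_cohort

    spec = cohort_preset("dorset", outcome_mode=OutcomeMode("from_model"))
    return generate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def large_model_cohort():
    """Large perfectly calibrated cohort for asymptotic checks (n = 50,000)."""
    from idiomval import OutcomeMode, cohort_preset, generate_cohort

    spec = cohort_preset("dorset", n=50_000, outcome_mode=OutcomeMode("from_model"))
    return generate_cohort(spec, seed=1)
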