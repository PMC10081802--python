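import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tbisens as tb

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return tb.default_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with default study conditions, prepared
    (scored, GOSE merged, grouping columns attached)."""
    cohort = tb.generate_cohort(tb.SimulationConfig(n_subjects=400), seed=101)
    return tb.prepare_cohort(cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
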