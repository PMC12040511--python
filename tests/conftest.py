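import numpy as np
import pytest

from cmtcalf import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 20+20 cohort, shared across read-only tests."""
    cohort, truth = simulate_cohort(CohortConfig(seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def patients_only():
    """A patients-only cohort of completers (no dropout)."""
    cohort, truth = simulate_cohort(CohortConfig(
        seed=17, n_patients=40, n_controls=0,
        dropout_prob_per_visit=(0.0, 0.0, 0.0)))
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
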