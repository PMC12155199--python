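import warnings

import pytest

import mecfstrial as m

# statsmodels emits convergence chatter on small simulated fits; keep the
# suite output readable without hiding our own warnings
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Fully retained 40-participant cohort with planted strata (17/18/5)
    and no noise: stratification recovers the plant exactly."""
    cfg = m.SyntheticCohortConfig.completers()
    return m.generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def zero_noise_deltas(zero_noise_cohort):
    scored = m.score_cohort(zero_noise_cohort)
    return m.compute_cohort_deltas(scored)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Study-structure cohort with default noise and dropout."""
    cfg = m.SyntheticCohortConfig.study_defaults()
    return m.generate_cohort(cfg, seed=7)
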