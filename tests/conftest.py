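import pytest

from prpecon import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale cohort: 20 patients, half bilateral, one single-injection patient."""
    return generate_cohort(SyntheticConfig(seed=1, n_patients=20, bilateral_fraction=0.5))


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for parameter-recovery checks."""
    return generate_cohort(SyntheticConfig(seed=7, n_patients=200, measurement_cv=0.05))
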