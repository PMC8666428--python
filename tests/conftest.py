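import matplotlib

matplotlib.use("Agg")

import pytest

from rpscore import SynthConfig, derive_score, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-size cohort with the planted response effects."""
    return generate_cohort(SynthConfig(seed=11)).table


@pytest.fixture(scope="session")
def big_planted_cohort():
    """Large planted cohort for low-variance distributional checks."""
    return generate_cohort(SynthConfig(n_patients=2000, seed=19)).table


@pytest.fixture(scope="session")
def ridge_derivation(planted_cohort):
    """One shared ridge score derivation (50 repeats) on the planted cohort."""
    return derive_score(planted_cohort, n_repeats=50, master_seed=23)
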