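import numpy as np
import pytest
from hypothesis import settings

from osteomap import cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study_cohort():
    """Default 40-patient study-emulation cohort (29 F / 11 M, 14/26 mix)."""
    return cohort.generate_cohort(cohort.default_study_spec(seed=1))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Large cohort with the whole-population effect profile, for
    parameter-recovery checks (n=500, multiplicative noise sd 0.02)."""
    spec = cohort.CohortSpec(
        n_patients=500, n_female=360, n_male=140, effect_noise_sd=0.02, seed=7
    )
    return cohort.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
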