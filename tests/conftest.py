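import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gazedys.core import clean_trial, exclude_short
from gazedys.features import extract_cohort_features
from gazedys.simulate import CohortConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=150,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Seed defining the reference synthetic cohort used across the suite.
COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort_trials():
    """The default 30-subject x 13-CC synthetic cohort (390 trials)."""
    return generate_cohort(CohortConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cleaned_trials(cohort_trials):
    return exclude_short([clean_trial(t) for t in cohort_trials])


@pytest.fixture(scope="session")
def cohort_features(cleaned_trials):
    """(records, events) feature tables for the default cohort."""
    return extract_cohort_features(cleaned_trials)


@pytest.fixture(scope="session")
def cohort_records(cohort_features):
    return cohort_features[0]


@pytest.fixture(scope="session")
def small_cohort_config():
    """A 4-subject cohort for fast end-to-end runs."""
    return CohortConfig(n_subjects=4, n_dyslexic=2, lines_per_segment=3,
                        words_per_line=6, seed=11)
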