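import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from vancopk import cohort, pk
from vancopk.fit import final_model_spec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def final_params():
    return pk.FINAL_MODEL_PARAMS


@pytest.fixture(scope="session")
def final_spec():
    return final_model_spec()


@pytest.fixture(scope="session")
def study_cohort(final_params):
    """One 94-infant synthetic study dataset (the default design)."""
    return cohort.make_cohort(cohort.CohortDesign(seed=0), final_params)


@pytest.fixture(scope="session")
def small_cohort(final_params):
    """A 20-infant dataset for fast estimation tests."""
    return cohort.make_cohort(cohort.CohortDesign(seed=42, n_subjects=20), final_params)
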