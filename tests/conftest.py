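import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from punchkan import cohort as ch
from punchkan import pipeline

warnings.filterwarnings("ignore", message="high_cut")


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 3 conditions x 8 punches; enough for pipeline plumbing."""
    cfg = ch.CohortConfig(n_subjects=6, punch_count_per_session=8)
    return ch.generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_kinetics(small_cohort):
    return pipeline.extract_kinetics(small_cohort)


@pytest.fixture(scope="session")
def small_envelopes(small_cohort):
    return pipeline.preprocess_cohort(small_cohort)


@pytest.fixture(scope="session")
def lnmes_spec():
    return ch.default_condition_specs()["L-NMES"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
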