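import io

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from morphoscore import (
    GroupDistributionSpec,
    PipelineConfig,
    fit_pipeline,
    read_morphokinetic_table,
    simulate_cohort,
)

SMALL_CSV = """embryo_id,patient_id,t2,t3,t4,t5,blastocyst
E1,P1,26.2,37.8,39.2,53.6,1
E2,P1,30.1,38.5,42.2,50.3,0
E3,P2,24.4,34.7,36.0,48.1,1
"""


@pytest.fixture
def small_csv():
    return SMALL_CSV


@pytest.fixture
def small_table():
    return read_morphokinetic_table(io.StringIO(SMALL_CSV))


@pytest.fixture(scope="session")
def default_spec():
    return GroupDistributionSpec()


@pytest.fixture(scope="session")
def cohort_2000(default_spec):
    """Default-condition synthetic derivation cohort (n = 2000, fixed seed)."""
    return simulate_cohort(default_spec, 2000, seed=11)


@pytest.fixture(scope="session")
def fit_2000(cohort_2000):
    """Full pipeline fit on the n = 2000 cohort (descriptives skipped for
    speed; they are exercised separately)."""
    return fit_pipeline(cohort_2000, PipelineConfig(seed=11, descriptives=False))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
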