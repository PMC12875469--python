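import numpy as np
import pytest

from modsense.cohort import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def cohort10k():
    """Large synthetic cohort at default (full-mediation) parameters,
    shared across calibration and mediation tests."""
    return generate_cohort(CohortParams(n=10_000), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
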