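import numpy as np
import pytest
from hypothesis import settings

from actipat.features import assemble_feature_table
from actipat.synthetic import CohortSpec, cohort_frames, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged default synthetic cohort at n=200 (fixed seed)."""
    return generate_cohort(CohortSpec(n_patients=200, seed=0))


@pytest.fixture(scope="session")
def default_frames(default_cohort):
    return cohort_frames(default_cohort)


@pytest.fixture(scope="session")
def table_w7(default_frames):
    daily, patients = default_frames
    table, excluded = assemble_feature_table(daily, patients, 7)
    assert not excluded
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
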