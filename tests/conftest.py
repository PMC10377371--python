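import numpy as np
import pytest

from icgperf.synthetic_data import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One 68x5 synthetic cohort under the default study conditions."""
    return generate_cohort(SyntheticCohortConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
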