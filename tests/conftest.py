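import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icusim import from_class_counts, HIRID_LOS_CLASS_COUNTS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: fixed seed for every stochastic test in the suite
SUITE_SEED = 12345


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def hirid_dist():
    """LOS class distribution of the reference ICU cohort."""
    return from_class_counts(HIRID_LOS_CLASS_COUNTS)
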