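import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kinimage import CohortConfig, generate_cohort
from kinimage.experiments import build_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """Compact strong-effect cohort: 6 stroke + 5 control participants,
    one activity -> 44 recordings.  Default deficit magnitudes."""
    return generate_cohort(CohortConfig(n_stroke=6, n_control=5, activities=("SC",), seed=7))


@pytest.fixture(scope="session")
def small_group2(small_cohort):
    return build_dataset(small_cohort, ("FN", "MPH"), "group2")


@pytest.fixture(scope="session")
def default_cohort():
    """The full reference design: 35 stroke + 19 control x 2 limbs x 3
    activities = 324 recordings."""
    return generate_cohort(CohortConfig(seed=2024))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
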