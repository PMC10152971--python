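import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from cvemp.calibration import StaircaseProtocol  # noqa: E402
from cvemp.simulate import CohortConfig, WaveformConfig, sample_cohort  # noqa: E402


@pytest.fixture(scope="session")
def protocol():
    return StaircaseProtocol()


@pytest.fixture(scope="session")
def wconfig():
    return WaveformConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Two dozen children plus a few adults; enough for feature round trips."""
    return sample_cohort(CohortConfig(n_children=24, n_adults=4), seed=7)


@pytest.fixture(scope="session")
def child(small_cohort):
    return next(s for s in small_cohort if s.group == "child")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
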