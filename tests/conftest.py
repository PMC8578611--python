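import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mea3d import MaterialSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mats() -> MaterialSet:
    return MaterialSet()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
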