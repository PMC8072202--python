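import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmdsim import DMDGeometry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def geom() -> DMDGeometry:
    """Default device: 7.56 um gap-free pitch, +-12 deg tilt, 50 x 50 mirrors."""
    return DMDGeometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
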