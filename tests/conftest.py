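import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oitkit import SynthConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic benchmark: 5 subjects x 6 activities x 2 units
    (accelerometer + gyroscope), 25 Hz, 60 s per recording, seed 0."""
    return generate_dataset(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A fast dataset for plumbing tests: 2 subjects x 3 activities x 1 unit,
    15 s recordings."""
    return generate_dataset(
        SynthConfig(n_subjects=2, n_activities=3, n_units=1, duration_s=15.0, seed=1)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
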