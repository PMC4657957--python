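import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from tileunwrap import SyntheticSpec, gaussian_ground_truth, make_wrapped  # noqa: E402


@pytest.fixture(scope="session")
def small_spec():
    """A 150-pixel analogue of the benchmark surface: same shape, same wrap
    count, cheap enough for unit tests."""
    return SyntheticSpec(n=150)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return gaussian_ground_truth(small_spec)


@pytest.fixture(scope="session")
def small_wrapped(small_truth):
    return make_wrapped(small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
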