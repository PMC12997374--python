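import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spiralselect import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    """A compact cohort used by tests that only need structure."""
    return SyntheticSpec(n_samples=150, n_numeric=4, n_nominal=4,
                        informative_idx=frozenset({0, 2, 5}),
                        missing_rate=0.05, seed=42)


@pytest.fixture(scope="session")
def small_ds(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def bench_spec():
    """The default CKD-like benchmark cohort."""
    return SyntheticSpec(seed=3)


@pytest.fixture(scope="session")
def bench_ds(bench_spec):
    return generate_dataset(bench_spec)


class FixedRng:
    """Deterministic stand-in for numpy Generator in operator tests."""

    def __init__(self, value: float = 1.0):
        self.value = value

    def random(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def uniform(self, lo, hi, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def fixed_rng():
    return FixedRng
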