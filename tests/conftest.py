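import numpy as np
import pytest

from tumorpipe.config import default_config
from tumorpipe.synthetic import PhantomSpec, TumorSpec, make_cohort


@pytest.fixture
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def base_spec():
    # geometry of the base tumor is jittered per cohort sample; only the
    # intensity delta is taken from here
    return PhantomSpec(
        tumor=TumorSpec(center=(0.0, 0.0), semi_axes=(1.0, 1.0), intensity_delta=80.0)
    )


@pytest.fixture(scope="session")
def small_cohorts(base_spec):
    """A (train, test) cohort pair shared by the slower end-to-end tests."""
    train = make_cohort(40, 0.5, base_spec=base_spec, seed=9001)
    test = make_cohort(20, 0.5, base_spec=base_spec, seed=9002)
    return train, test


def random_histogram(rng: np.random.Generator, n: int = 256) -> np.ndarray:
    """Sparse-ish random histogram with a guaranteed two occupied levels."""
    counts = np.zeros(n, dtype=np.int64)
    k = rng.integers(2, n // 2)
    levels = rng.choice(n, size=k, replace=False)
    counts[levels] = rng.integers(1, 500, size=k)
    return counts
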