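import numpy as np
import pytest

from ictalwave import SyntheticConfig, generate_dataset
from ictalwave.io import segments_to_arrays


@pytest.fixture(scope="session")
def theta_dataset():
    """Default study conditions: 6 subjects, 20 windows/class, theta effect."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def theta_arrays(theta_dataset):
    return segments_to_arrays(theta_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast dataset for estimator/CLI-level tests."""
    return generate_dataset(
        SyntheticConfig(n_subjects=3, segments_per_class_per_subject=6, seed=1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
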