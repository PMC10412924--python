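import numpy as np
import pytest

from mfvan import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def default_dataset(default_spec):
    """The default synthetic dataset (10 subjects x 12 pairs, 64 px)."""
    samples, manifest = generate_dataset(default_spec)
    return samples, manifest


@pytest.fixture(scope="session")
def small_spec():
    """A reduced generation spec for fast unit tests."""
    return SyntheticSpec(image_size=32, n_subjects=3, samples_per_subject=6, region_size=6, seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    samples, manifest = generate_dataset(small_spec)
    return samples, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(123)
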