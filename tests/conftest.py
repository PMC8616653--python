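import numpy as np
import pytest

from fissureseg.data_io import Sample
from fissureseg.synthetic import SyntheticParams, generate_dataset


@pytest.fixture(scope="session")
def small_params():
    """Generator settings shared by the fast tests: 64x64 canvas."""
    return SyntheticParams(image_size=(64, 64))


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """Eight 64x64 synthetic samples, generated once per session."""
    return generate_dataset(small_params, 8, seed=11)


@pytest.fixture()
def asym_sample():
    """A deliberately asymmetric labeled sample (no dihedral symmetry)."""
    rng = np.random.default_rng(3)
    image = rng.integers(0, 256, size=(6, 6, 3), dtype=np.uint8)
    image[0, 0] = [255, 0, 0]  # pin one corner so all 8 orbit images differ
    mask = np.zeros((6, 6), dtype=np.uint8)
    mask[0, 1] = 1
    mask[2, 3] = 1
    return Sample(image, mask, identifier="asym")
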