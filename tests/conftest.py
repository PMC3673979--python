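import numpy as np
import pytest

from infuseg import BinaryMask, PhantomSpec, VoxelGrid, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(1)


@pytest.fixture()
def random_grid(rng):
    return VoxelGrid(rng.normal(100.0, 25.0, (10, 12, 8)), (0.7, 0.7, 1.0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, shoulder-free, distractor-free phantom: two-valued image."""
    spec = PhantomSpec(shoulder_sigma_mm=0.0, noise_sigma=0.0,
                       bg_texture_amp=0.0, n_background_blobs=0)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=7))


def random_mask(rng, shape=(20, 20, 20), p=0.3):
    return BinaryMask(rng.random(shape) < p, (1.0, 1.0, 1.0))
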