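import numpy as np
import pytest

from echoseg.phantom import PhantomParams, make_dataset, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def rest_phantom():
    """Default rest-stage phantom, seed 1 (shared, read-only)."""
    return make_phantom(PhantomParams(), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """4 patients x 2 small images with 3 operators each (shared, read-only)."""
    images, manifest = make_dataset(
        4,
        images_per_patient=2,
        seed=7,
        size_range=((60, 70), (70, 82)),
        spacing_mean=1.4,
        spacing_sd=0.1,
    )
    return images, manifest


def random_blob_mask(shape, rng, n_blobs=1):
    """Union of random filled discs; may touch borders."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    rows, cols = np.mgrid[0:H, 0:W]
    for _ in range(n_blobs):
        r0, c0 = rng.uniform(0, H), rng.uniform(0, W)
        rad = rng.uniform(2, min(H, W) / 3)
        mask |= (rows - r0) ** 2 + (cols - c0) ** 2 <= rad**2
    return mask
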