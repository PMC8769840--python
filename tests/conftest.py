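import numpy as np
import pytest

from wbckit.synthdata import SmearSpec, make_smear


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def blob_image():
    """Four Gaussian blobs of distinct scales on a flat background."""
    img = np.zeros((128, 128))
    yy, xx = np.mgrid[0:128, 0:128]
    for y, x, s, a in [(40, 40, 4, 1.0), (80, 90, 6, 0.8), (100, 30, 3, 0.9), (30, 100, 5, 0.7)]:
        img += a * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * s * s))
    return img


@pytest.fixture(scope="session")
def blob_centers():
    return [(40, 40), (80, 90), (100, 30), (30, 100)]


@pytest.fixture(scope="session")
def smear_pair():
    """One default-size synthetic smear with its ground-truth mask."""
    return make_smear(SmearSpec(seed=7))


def random_mask_pair(rng, shape=(24, 24), p=0.35):
    """A pair of random but overlapping non-empty masks."""
    base = rng.random(shape) < p
    flip = rng.random(shape) < 0.1
    other = base ^ flip
    if not base.any():
        base[shape[0] // 2, shape[1] // 2] = True
    if not other.any():
        other[shape[0] // 2, shape[1] // 2] = True
    return base, other
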