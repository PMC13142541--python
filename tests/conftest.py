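import numpy as np
import pytest

from poca import ImageSimConfig, ImagePair


@pytest.fixture
def small_image_config() -> ImageSimConfig:
    """A fast 128x128 field with ~40 puncta, for unit tests."""
    return ImageSimConfig(field_shape=(4, 128, 128), n_nuclei=2,
                          nucleus_radius=2000.0, puncta_per_nucleus=20.0,
                          seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_pair(rng: np.random.Generator, n: int = 32,
                pixel_size: float = 100.0) -> ImagePair:
    """A random non-negative image pair (shared structure plus noise)."""
    base = rng.gamma(2.0, 5.0, size=(n, n))
    a = base + rng.normal(0, 1.0, (n, n))
    b = base + rng.normal(0, 1.0, (n, n))
    return ImagePair(target=np.clip(a, 0, None), deposition=np.clip(b, 0, None),
                     pixel_size=pixel_size)
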