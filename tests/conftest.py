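import numpy as np
import pytest

from sarftex import GrayImage, TabularSpec, TextureClassSpec, gen_tabular, gen_texture_dataset


@pytest.fixture
def tiny_image() -> GrayImage:
    return GrayImage(np.array([[1, 2], [3, 4]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grating_entries():
    """Two-class oriented-grating set (small; shared across tests)."""
    specs = [
        TextureClassSpec(name="horiz", orientation=0, n_images=10),
        TextureClassSpec(name="vert", orientation=90, n_images=10),
    ]
    return gen_texture_dataset(specs, seed=42)


@pytest.fixture(scope="session")
def tabular_data():
    """Tabular features with a known informative/noise split."""
    X, y, informative = gen_tabular(TabularSpec(n_samples=200, seed=7))
    return X, y, informative
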