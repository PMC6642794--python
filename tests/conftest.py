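import numpy as np
import pytest

from viscomp.image_features import ChannelPlane
from viscomp.synthetic import ImageRecipe, TableRecipe, make_feature_table, make_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_plane(rng):
    """A seeded 64x64 uniform-noise plane."""
    return ChannelPlane(rng.uniform(0, 1, size=(64, 64)), "V")


@pytest.fixture
def smooth_plane(rng):
    """Smoothed noise: enough structure that coders at different fidelity
    levels actually differ."""
    from scipy import ndimage
    raw = rng.uniform(0, 1, size=(64, 64))
    sm = ndimage.gaussian_filter(raw, sigma=3.0)
    sm = (sm - sm.min()) / (sm.max() - sm.min())
    return ChannelPlane(sm, "V")


@pytest.fixture
def checkerboard():
    return make_image(ImageRecipe(kind="checkerboard", size=(64, 64), cell=8))


@pytest.fixture
def flat_gray():
    return make_image(ImageRecipe(kind="flat", size=(32, 32), value=128))


@pytest.fixture(scope="session")
def small_table():
    """150 samples, 6 groups, 2 informative — shared across model tests."""
    recipe = TableRecipe(n_samples=150, n_groups=6, informative_groups=2, seed=3)
    X, y, truth = make_feature_table(recipe)
    return X, y, truth
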