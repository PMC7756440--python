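import numpy as np
import pytest

from wiltscan import generate_scene
from wiltscan.scene import SceneConfig


@pytest.fixture(scope="session")
def small_config():
    return SceneConfig(grid_rows=80, grid_cols=80, coarse_factor=20, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def noisefree_config():
    return SceneConfig(
        grid_rows=60,
        grid_cols=60,
        coarse_factor=20,
        noise_sd=0.0,
        pixel_offset_sd=0.0,
        cloud_gap_prob=0.0,
        seed=9,
    )


@pytest.fixture(scope="session")
def noisefree_scene(noisefree_config):
    return generate_scene(noisefree_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
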