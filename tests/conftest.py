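import numpy as np
import pytest

from qdki67 import SceneParams, WavelengthGrid, build_default_library


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def library(grid):
    return build_default_library(grid)


@pytest.fixture
def small_scene():
    """A fast 64x64 field with a single nest, suited to exactness checks."""
    return SceneParams(
        height=64, width=64, n_nests=1, nest_axes=(12.0, 18.0),
        nuclei_radius=2.0, nuclei_density=0.03,
        proliferation_fraction=0.4, noise_sd=0.0, seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
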