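import numpy as np
import pytest

from canopysim import (
    LightSourceSpec,
    Scene,
    SceneLayout,
    SoilTileGrid,
    uniform_grid,
)
from canopysim.fixtures import _rosette_with_leaf, _small_layout


@pytest.fixture
def small_layout() -> SceneLayout:
    return _small_layout()


@pytest.fixture
def empty_scene(small_layout) -> Scene:
    return Scene([], small_layout)


@pytest.fixture
def small_tiles(small_layout) -> SoilTileGrid:
    return SoilTileGrid(region=small_layout.plot_bounds, nx=4, ny=4)


@pytest.fixture
def vertical_source() -> LightSourceSpec:
    return LightSourceSpec(n_rays=20_000, angular_model="vertical", seed=7)


@pytest.fixture
def diffuse_source() -> LightSourceSpec:
    return LightSourceSpec(n_rays=20_000, seed=7)


def random_mini_canopy(seed: int, n: int = 3, spacing: float = 0.02) -> Scene:
    """A small randomized stand of single-leaf rosettes for property tests."""
    rng = np.random.default_rng(seed)
    layout = uniform_grid(n, n, spacing)
    plants = []
    for i, (x, y) in enumerate(layout.canopy_positions):
        plants.append(_rosette_with_leaf(
            (float(x), float(y)),
            lamina_length_mm=rng.uniform(5, 25),
            lamina_width_mm=rng.uniform(3, 12),
            petiole_length_mm=rng.uniform(0, 10),
            angle=rng.uniform(0, 80),
            azimuth=rng.uniform(0, 360),
            plant_id=i,
        ))
    return Scene(plants, layout)
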