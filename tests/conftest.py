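import numpy as np
import pytest
from hypothesis import settings

from spinedef import SpineMap, TrunkSurface, syndrome_presets

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def surface30() -> TrunkSurface:
    return TrunkSurface(circumference_cm=30.0, height_cm=30.0)


@pytest.fixture
def empty_map(surface30) -> SpineMap:
    return SpineMap.empty(surface30, species_id="empty")


@pytest.fixture
def lattice_map(surface30) -> SpineMap:
    """Spines on a 1-cm square lattice covering the whole surface."""
    xs, ys = np.meshgrid(np.arange(0.0, 30.0, 1.0), np.arange(0.0, 30.0, 1.0))
    return SpineMap(surface30, xs.ravel(), ys.ravel(), np.zeros(xs.size),
                    species_id="lattice")


@pytest.fixture
def map_a() -> SpineMap:
    """Small two-spine reference map (C=12, H=12)."""
    return SpineMap(TrunkSurface(12.0, 12.0), np.array([3.0, 9.0]),
                    np.array([3.0, 9.0]), np.zeros(2), species_id="mapA")


@pytest.fixture
def presets():
    return syndrome_presets()


def random_map(rng, max_spines=20, cmin=10.0, cmax=25.0,
               grid_aligned=False) -> SpineMap:
    """Random sparse map; ``grid_aligned`` snaps the surface to dimensions
    whose quarter-circumference is a multiple of the default 0.5-cm raster,
    where the bite-size sweep is free of quantization wobble."""
    if grid_aligned:
        C = 4.0 * float(rng.integers(round(cmin / 4), round(cmax / 4) + 1))
        H = float(rng.integers(round(cmin), round(cmax) + 1))
    else:
        C = float(rng.uniform(cmin, cmax))
        H = float(rng.uniform(cmin, cmax))
    n = int(rng.integers(0, max_spines + 1))
    return SpineMap(TrunkSurface(C, H), rng.uniform(0, C, n),
                    rng.uniform(0, H, n), np.zeros(n), species_id="rand")
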