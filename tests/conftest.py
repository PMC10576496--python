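import numpy as np
import pytest

from reefstruct import ElevationRaster


@pytest.fixture
def flat_raster():
    """1 m² horizontal plane at 1 cm cells (100×100 grid)."""
    return ElevationRaster(np.full((100, 100), 2.5), 0.01)


def make_plane(slope_deg: float, n: int = 100, cell: float = 0.01) -> ElevationRaster:
    """Plane dipping east at the given angle from horizontal."""
    x = (np.arange(n) + 0.5) * cell
    z = np.tile(x * np.tan(np.radians(slope_deg)), (n, 1))
    return ElevationRaster(z, cell)


@pytest.fixture
def plane_factory():
    return make_plane


def seeded_rough_raster(seed: int, n: int = 64, cell: float = 0.01) -> ElevationRaster:
    """Generic rough surface for oracle comparisons (not fBm; plain noise)."""
    rng = np.random.default_rng(seed)
    return ElevationRaster(rng.normal(0.0, 0.05, (n, n)), cell)
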