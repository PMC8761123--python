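import numpy as np
import pytest

from bioregion import LandscapeSpec, RasterGrid, RasterStack, simulate_landscape
from bioregion.synthetic import default_collinear_blocks


@pytest.fixture(scope="session")
def tiny_landscape():
    """60×60 landscape, K_true=5, 6 base + 2 collinear variables, seed 7."""
    spec = LandscapeSpec(seed=7, collinear_blocks=default_collinear_blocks(2))
    stack, truth = simulate_landscape(spec)
    return spec, stack, truth


@pytest.fixture
def small_grid():
    """5×5 georeferenced grid with one nodata cell."""
    values = np.arange(25, dtype=float).reshape(5, 5)
    mask = np.zeros((5, 5), dtype=bool)
    mask[0, 0] = True
    return RasterGrid(values, mask, (10.0, 50.0, 0.5, -0.5), "EPSG:4326")


def make_grid(values, mask=None, geotransform=(0.0, 10.0, 1.0, -1.0), crs="EPSG:4326"):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return RasterGrid(values, np.asarray(mask, dtype=bool), geotransform, crs)


def make_stack(arrays, codes=None, **kwargs):
    codes = codes or [f"v{i}" for i in range(len(arrays))]
    return RasterStack([(c, make_grid(a, **kwargs)) for c, a in zip(codes, arrays)])
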