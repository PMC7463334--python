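import numpy as np
import pandas as pd
import pytest

from reefscape.grids import GridSpec, RasterSeries
from reefscape.genotypes import GenotypeMatrix


@pytest.fixture
def small_grid():
    return GridSpec(origin_lon=127.0, origin_lat=28.0, cell_size_km=5.0, rows=6, cols=6)


def make_series(grid, values, mask=None, start="2001-01-01", freq="D", name="var"):
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones(grid.shape, bool)
    times = pd.date_range(start, periods=values.shape[0], freq=freq)
    return RasterSeries(grid=grid, times=times, values=values, mask=mask, name=name)


@pytest.fixture
def constant_series(small_grid):
    vals = np.full((60, 6, 6), 20.0)
    return make_series(small_grid, vals)


def toy_matrix(codes, sites=None):
    """GenotypeMatrix from a small 2-D code array."""
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    if sites is None:
        sites = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    individuals = pd.DataFrame({
        "id": [f"ind{i}" for i in range(n)],
        "site": sites,
        "lon": 127.0,
        "lat": 28.0,
    })
    snps = pd.DataFrame({
        "scaffold": ["s1"] * L,
        "pos": np.arange(1, L + 1) * 100,
        "ref": "A",
        "alt": "T",
    })
    return GenotypeMatrix(codes=codes, individuals=individuals, snps=snps)
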