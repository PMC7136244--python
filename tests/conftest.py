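import numpy as np
import pandas as pd
import pytest

from bioadvect.geofields import FieldSeries, GeoGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_grid():
    """5x6 quarter-degree grid around 70N with a land corner."""
    lat = 69.0 + 0.25 * np.arange(5)
    lon = 19.0 + 0.25 * np.arange(6)
    land = np.zeros((5, 6), dtype=bool)
    land[0, 0] = True
    return GeoGrid(lat_centers=lat, lon_centers=lon, spacing_deg=0.25, land_mask=land)


@pytest.fixture
def all_ocean_grid():
    lat = 60.0 + 0.5 * np.arange(8)
    lon = 10.0 + 0.5 * np.arange(10)
    return GeoGrid(lat_centers=lat, lon_centers=lon, spacing_deg=0.5)


def make_series(grid, values, start="2000-01-01", freq="D", **kw):
    times = pd.date_range(start, periods=values.shape[0], freq=freq).values
    return FieldSeries(grid=grid, times=times, values=values, **kw)


@pytest.fixture
def make_field_series():
    return make_series
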