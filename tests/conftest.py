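import numpy as np
import pandas as pd
import pytest

from physiosdm.coldstress import ProfileSeries, SoilTempSeries
from physiosdm.grids import GridDef, Raster


@pytest.fixture
def small_grid() -> GridDef:
    """10 x 10 grid of 0.1-degree cells anchored at (85E, 32N)."""
    return GridDef(west_lon=85.0, north_lat=32.0, n_rows=10, n_cols=10, cell_size=0.1)


@pytest.fixture
def flat_raster(small_grid) -> Raster:
    return Raster(small_grid, np.zeros(small_grid.shape), "flat")


def make_profile(
    temps,
    start="2019-11-01T00:00",
    station_id="S000",
    lon=85.05,
    lat=31.95,
    elevation=4000.0,
):
    """3-hourly single-depth profile starting at `start`."""
    temps = np.asarray(temps, dtype=float)
    t0 = np.datetime64(start, "s")
    timestamps = t0 + np.arange(temps.size) * np.timedelta64(3, "h")
    return ProfileSeries(
        station_id=station_id, lon=lon, lat=lat, elevation=elevation,
        timestamps=timestamps, temps=temps,
    )


def make_station(
    depth_temps: dict,
    start="2019-11-01T00:00",
    station_id="S000",
    lon=85.05,
    lat=31.95,
    elevation=4000.0,
):
    """Multi-depth 3-hourly station series from {depth_cm: temp array}."""
    depths = sorted(depth_temps)
    temps = np.vstack([np.asarray(depth_temps[d], dtype=float) for d in depths])
    t0 = np.datetime64(start, "s")
    timestamps = t0 + np.arange(temps.shape[1]) * np.timedelta64(3, "h")
    return SoilTempSeries(
        station_id=station_id, lon=lon, lat=lat, elevation=elevation,
        depths=[float(d) for d in depths], timestamps=timestamps, temps=temps,
    )


@pytest.fixture
def occurrence_frame():
    return pd.DataFrame(
        {
            "species": ["A", "A", "B"],
            "lon": [85.05, 85.15, 85.05],
            "lat": [31.95, 31.95, 31.95],
            "source": ["field", "field", "lit"],
        }
    )
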