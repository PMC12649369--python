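"""Overwintering cold-stress statistic from sub-daily soil temperatures.

The physiological predictor is built from 3-hourly, multi-depth soil
temperature records.  A *cold-stress event* is a 3-hour interval whose
depth-averaged soil temperature falls strictly below the species' critical
thermal minimum (CT_min); a *cold-stress day* is a calendar day containing
at least one event; the *cold-stress frequency* at a location is the number
of such days over the overwintering window (1 November–31 March).  Station
frequencies are interpolated to the predictor grid by inverse-distance
weighting, giving a raster that enters the suitability models alongside
climate and terrain.

Stations with any missing in-window reading are dropped rather than
gap-filled, matching standard event-counting practice: an imputed interval
could silently create or destroy an event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grids import GridDef, Raster

logger = logging.getLogger(__name__)

#: 3-hour sampling: intervals per day.
INTERVALS_PER_DAY = 8
STEP = np.timedelta64(3, "h")

#: Default depth band (cm) over which soil temperature is averaged for the
#: event definition.
DEFAULT_DEPTH_RANGE = (10.0, 40.0)


@dataclass
class SoilTempSeries:
    """Per-station, per-depth 3-hourly soil temperature records.

    ``temps`` has shape (n_depths, n_timestamps); missing readings are NaN.
    Timestamps mark the start of each 3-h interval and must be strictly
    increasing and equally spaced at 3 h.
    """

    station_id: str
    lon: float
    lat: float
    elevation: float
    depths: list[float]
    timestamps: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.temps = np.atleast_2d(np.asarray(self.temps, dtype=float))
        if self.temps.shape != (len(self.depths), self.timestamps.size):
            raise ValueError(
                f"temps shape {self.temps.shape} != (n_depths={len(self.depths)}, "
                f"n_timestamps={self.timestamps.size})"
            )
        if self.timestamps.size > 1:
            diffs = np.diff(self.timestamps)
            if not np.all(diffs == STEP):
                raise ValueError("timestamps must be strictly increasing at a 3-h step")


@dataclass
class ProfileSeries:
    """A single depth-averaged temperature profile (one value per interval)."""

    station_id: str
    lon: float
    lat: float
    elevation: float
    timestamps: np.ndarray
    temps: np.ndarray
    depth_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.shape != self.timestamps.shape:
            raise ValueError("temps and timestamps must be aligned 1-D arrays")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.temps).sum())


@dataclass(frozen=True)
class OverwinterWindow:
    """The hibernation window, 00:00 on 1 Nov through 23:00 on 31 Mar.

    ``year_policy`` controls which calendar years the window spans:

    - ``"spanning"`` (default): 1 Nov of ``year`` to 31 Mar of ``year + 1``,
      the natural reading of a single winter.
    - ``"single_year"``: Nov–Dec and Jan–Mar both taken from ``year`` — the
      composite window implied by a dataset restricted to one calendar year
      of observations.

    The last included interval starts at 21:00 on 31 March (3-h interval
    timestamps mark interval starts), so "through 23:00" means through the
    21:00–24:00 interval.
    """

    year: int
    year_policy: str = "spanning"

    def __post_init__(self) -> None:
        if self.year_policy not in ("spanning", "single_year"):
            raise ValueError(f"unknown year_policy {self.year_policy!r}")

    @property
    def spring_year(self) -> int:
        return self.year + 1 if self.year_policy == "spanning" else self.year

    @property
    def start(self) -> np.datetime64:
        return np.datetime64(f"{self.year}-11-01T00:00", "s")

    @property
    def end(self) -> np.datetime64:
        # start of the last 3-h interval of 31 March
        return np.datetime64(f"{self.spring_year}-03-31T21:00", "s")

    @property
    def n_days(self) -> int:
        feb29 = 1 if _is_leap(self.spring_year) else 0
        return 30 + 31 + 31 + 28 + feb29 + 31  # Nov Dec Jan Feb Mar

    @property
    def n_intervals(self) -> int:
        return self.n_days * INTERVALS_PER_DAY

    def contains(self, timestamps: np.ndarray) -> np.ndarray:
        t = np.asarray(timestamps, dtype="datetime64[s]")
        if self.year_policy == "spanning":
            return (t >= self.start) & (t <= self.end)
        autumn_end = np.datetime64(f"{self.year}-12-31T21:00", "s")
        spring_start = np.datetime64(f"{self.year}-01-01T00:00", "s")
        return ((t >= self.start) & (t <= autumn_end)) | (
            (t >= spring_start) & (t <= self.end)
        )


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


@dataclass
class PopulationCTmin:
    """CT_min summary statistics for one sampled population."""

    name: str
    n: int
    mean: float
    min: float
    max: float
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"population {self.name!r}: n must be positive")
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"population {self.name!r}: min <= mean <= max violated")


@dataclass
class CTminSummary:
    """Pooled critical-thermal-minimum summary across populations."""

    populations: list[PopulationCTmin]
    pooled_value: float
    overall_range: float


@dataclass
class StressResult:
    """Cold-stress counts for one station over one overwintering window."""

    station_id: str
    lon: float
    lat: float
    n_events: int
    n_stress_days: int
    window: OverwinterWindow
    ctmin_used: float
    elevation: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.n_stress_days <= self.window.n_days:
            raise ValueError("n_stress_days outside [0, days-in-window]")
        if not self.n_stress_days <= self.n_events <= INTERVALS_PER_DAY * self.window.n_days:
            raise ValueError("n_events inconsistent with n_stress_days / window length")


def depth_average(
    series: SoilTempSeries, depth_range: tuple[float, float] = DEFAULT_DEPTH_RANGE
) -> ProfileSeries:
    """Unweighted mean over the depths inside ``depth_range`` (inclusive).

    A timestamp missing at any included depth is missing in the profile:
    an average over a partial profile would bias the event count.
    """
    low, high = depth_range
    idx = [i for i, d in enumerate(series.depths) if low <= d <= high]
    if not idx:
        raise ValueError(
            f"no depth of {series.depths} inside range [{low}, {high}] cm"
        )
    sub = series.temps[idx, :]
    profile = np.where(np.any(np.isnan(sub), axis=0), np.nan, sub.mean(axis=0))
    return ProfileSeries(
        station_id=series.station_id,
        lon=series.lon,
        lat=series.lat,
        elevation=series.elevation,
        timestamps=series.timestamps,
        temps=profile,
        depth_range=(low, high),
    )


def clip_window(profile: ProfileSeries, window: OverwinterWindow) -> ProfileSeries:
    """Retain only the in-window intervals of a profile."""
    mask = window.contains(profile.timestamps)
    if not mask.any():
        raise ValueError(
            f"station {profile.station_id}: series does not overlap the "
            f"{window.year} overwintering window"
        )
    return ProfileSeries(
        station_id=profile.station_id,
        lon=profile.lon,
        lat=profile.lat,
        elevation=profile.elevation,
        timestamps=profile.timestamps[mask],
        temps=profile.temps[mask],
        depth_range=profile.depth_range,
    )


def drop_incomplete_stations(
    stations: list[SoilTempSeries],
    window: OverwinterWindow,
    depth_range: tuple[float, float] = DEFAULT_DEPTH_RANGE,
) -> list[SoilTempSeries]:
    """Remove stations missing any in-window 3-h reading at a required depth.

    A station is retained only if it covers every interval of the window at
    every depth inside ``depth_range`` with a non-missing value.  Removals
    are logged with the reason.
    """
    kept: list[SoilTempSeries] = []
    for st in stations:
        idx = [i for i, d in enumerate(st.depths) if depth_range[0] <= d <= depth_range[1]]
        if not idx:
            logger.warning("station %s dropped: no depth in range %s", st.station_id, depth_range)
            continue
        mask = window.contains(st.timestamps)
        n_in = int(mask.sum())
        if n_in < window.n_intervals:
            logger.warning(
                "station %s dropped: covers %d of %d window intervals",
                st.station_id, n_in, window.n_intervals,
            )
            continue
        n_missing = int(np.isnan(st.temps[np.ix_(idx, np.nonzero(mask)[0])]).sum())
        if n_missing:
            logger.warning(
                "station %s dropped: %d missing in-window readings", st.station_id, n_missing
            )
            continue
        kept.append(st)
    if not kept:
        logger.warning("no station survived the completeness screen")
    return kept


def count_stress(
    profile: ProfileSeries, ctmin: float, window: OverwinterWindow | None = None
) -> StressResult:
    """Count cold-stress events and days on a clipped, complete profile.

    An event is a 3-h interval with depth-averaged temperature strictly
    below ``ctmin`` ("fell below"); a profile sitting exactly at CT_min
    produces no events.  A stress day is a calendar day (of the series'
    own clock, naive UTC) containing at least one event.
    """
    if window is not None:
        profile = clip_window(profile, window)
    if profile.n_missing:
        raise ValueError(
            f"station {profile.station_id}: {profile.n_missing} missing values; "
            "drop incomplete stations before counting"
        )
    events = profile.temps < ctmin
    n_events = int(events.sum())
    days = profile.timestamps.astype("datetime64[D]")
    n_stress_days = int(np.unique(days[events]).size)
    if window is None:
        # infer the window from the clipped span for bound checking
        window = _window_from_span(profile.timestamps)
    return StressResult(
        station_id=profile.station_id,
        lon=profile.lon,
        lat=profile.lat,
        elevation=profile.elevation,
        n_events=n_events,
        n_stress_days=n_stress_days,
        window=window,
        ctmin_used=float(ctmin),
    )


def _window_from_span(timestamps: np.ndarray) -> OverwinterWindow:
    first = timestamps.min().astype("datetime64[Y]").astype(int) + 1970
    last = timestamps.max().astype("datetime64[Y]").astype(int) + 1970
    policy = "spanning" if last > first else "single_year"
    year = first if policy == "spanning" else last
    # fall back to spanning from the previous year when only spring is seen
    w = OverwinterWindow(year, policy)
    if not w.contains(timestamps).all():
        w = OverwinterWindow(first - 1, "spanning")
    return w


def interpolate_to_grid(
    results: list[StressResult],
    grid: GridDef,
    idw_power: float = 2.0,
    k_neighbors: int = 4,
    name: str = "cold_stress_frequency",
) -> Raster:
    """Inverse-distance-weighted interpolation of station stress days.

    Each cell takes the IDW mean (power ``idw_power``) of its ``k_neighbors``
    nearest stations' ``n_stress_days``; a cell whose centre coincides with
    a station reproduces the station value exactly.  ``k_neighbors = 1``
    gives nearest-neighbour interpolation.  Distances are Euclidean in
    degrees — adequate at the regional scales the statistic targets.
    """
    if not results:
        raise ValueError("no stations to interpolate")
    coords = np.array([[r.lon, r.lat] for r in results])
    vals = np.array([r.n_stress_days for r in results], dtype=float)
    k = min(k_neighbors, len(results))
    tree = cKDTree(coords)
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    lon, lat = grid.cell_center(rows.ravel(), cols.ravel())
    dist, idx = tree.query(np.column_stack([lon, lat]), k=k)
    dist = np.atleast_2d(dist.reshape(len(lon), k))
    idx = np.atleast_2d(idx.reshape(len(lon), k))
    out = np.empty(len(lon))
    exact = dist[:, 0] == 0.0
    out[exact] = vals[idx[exact, 0]]
    rest = ~exact
    if k == 1:
        out[rest] = vals[idx[rest, 0]]  # nearest-neighbour: exact, no round-off
    else:
        w = 1.0 / dist[rest] ** idw_power
        out[rest] = (w * vals[idx[rest]]).sum(axis=1) / w.sum(axis=1)
    return Raster(grid, out.reshape(grid.shape), name)


def pool_ctmin(populations: list[PopulationCTmin]) -> CTminSummary:
    """Pool per-population CT_min statistics.

    The pooled value is the sample-size-weighted mean of population means;
    the overall range is the global max minus the global min across
    populations.
    """
    if not populations:
        raise ValueError("at least one population required")
    n = np.array([p.n for p in populations], dtype=float)
    means = np.array([p.mean for p in populations])
    pooled = float((n * means).sum() / n.sum())
    overall = float(max(p.max for p in populations) - min(p.min for p in populations))
    return CTminSummary(populations=list(populations), pooled_value=pooled, overall_range=overall)


# ---------------------------------------------------------------------------
# station series I/O (long format CSV)

def stations_to_frame(stations: list[SoilTempSeries]) -> pd.DataFrame:
    """Long-format table: station_id, depth_cm, timestamp, temp_C."""
    parts = []
    for st in stations:
        for i, d in enumerate(st.depths):
            parts.append(
                pd.DataFrame(
                    {
                        "station_id": st.station_id,
                        "depth_cm": d,
                        "timestamp": st.timestamps,
                        "temp_C": st.temps[i],
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)


def stations_from_frame(
    series: pd.DataFrame, meta: pd.DataFrame
) -> list[SoilTempSeries]:
    """Rebuild station series from a long-format table plus a metadata table
    (station_id, lon, lat, elevation)."""
    meta = meta.set_index("station_id")
    out = []
    for sid, g in series.groupby("station_id", sort=True):
        piv = g.pivot_table(index="depth_cm", columns="timestamp", values="temp_C", dropna=False)
        m = meta.loc[sid]
        out.append(
            SoilTempSeries(
                station_id=str(sid),
                lon=float(m["lon"]),
                lat=float(m["lat"]),
                elevation=float(m["elevation"]),
                depths=[float(d) for d in piv.index],
                timestamps=piv.columns.to_numpy(dtype="datetime64[s]"),
                temps=piv.to_numpy(),
            )
        )
    return out
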