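"""Virtual landscapes, soil-temperature stations and virtual species.

The generator produces inputs with the statistical structure the analysis
assumes — spatially autocorrelated, cross-correlated climate surfaces; an
elevation surface with a regional trend; 3-hourly multi-depth soil
temperatures whose mean falls with elevation and whose diurnal cycle damps
with depth — together with a virtual species whose true suitability is the
product of smooth bell-shaped climate responses and a hard winter-survival
constraint (cold-stress days below a tolerance).  Because the truth is
known, every downstream stage (thinning, the cold-stress predictor,
screening, model fitting, habitat comparison) can be validated without any
external data.

All randomness flows from one explicit integer seed per operation; the same
(spec, grid, seed) triple yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .coldstress import OverwinterWindow, SoilTempSeries
from .grids import GridDef, Raster, check_same_grid
from .occurrences import OccurrenceSet

import pandas as pd


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic predictor stack.

    Climate surfaces are generated as Gaussian-smoothed white noise
    (correlation length ``spatial_correlation_length`` in cells),
    standardised, then linearly mixed to the target ``cross_correlation``
    matrix.  Elevation is a north–south trend between ``elev_high_m`` (north
    edge) and ``elev_low_m`` (south edge) plus smooth relief.
    """

    n_climate_vars: int = 6
    spatial_correlation_length: float = 8.0
    cross_correlation: np.ndarray | None = None
    elev_low_m: float = 3000.0
    elev_high_m: float = 5000.0
    elev_relief_m: float = 150.0
    #: correlation of the first climate surface (temperature-like) with
    #: elevation; negative because temperature falls with altitude.  Real
    #: bioclimatic temperature summaries are strong but imperfect elevation
    #: proxies, which is why a collinearity screen removes raw elevation
    #: while the retained climate surface still cannot pinpoint the
    #: winter-survival boundary.
    temp_elevation_corr: float = -0.85

    def correlation_matrix(self) -> np.ndarray:
        c = (
            np.eye(self.n_climate_vars)
            if self.cross_correlation is None
            else np.asarray(self.cross_correlation, dtype=float)
        )
        if c.shape != (self.n_climate_vars, self.n_climate_vars):
            raise ValueError("cross_correlation shape does not match n_climate_vars")
        if not np.allclose(c, c.T):
            raise ValueError("cross_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("cross_correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(c)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"cross_correlation is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        return c


@dataclass
class TempParams:
    """Parameters of the synthetic soil-temperature model.

    Temperature at depth index *i* and time *t* for a station at elevation
    *z* is::

        T = ref_mean_C - lapse_C_per_km * (z - ref_elevation_m)/1000
            - annual_amplitude_C * cos(2*pi*(doy - coldest_doy)/365.25)
            + diurnal_amplitude_C * depth_damping**i * cos(2*pi*(hour - 14)/24)
            + noise

    so the annual minimum falls on ``coldest_doy`` (mid-January by default),
    the diurnal maximum at 14:00, and the diurnal amplitude shrinks by the
    factor ``depth_damping`` at each successive depth in ``depths_cm``.
    """

    ref_mean_C: float = 8.0
    ref_elevation_m: float = 4000.0
    lapse_C_per_km: float = 6.5
    annual_amplitude_C: float = 8.0
    diurnal_amplitude_C: float = 4.0
    noise_sd_C: float = 1.0
    depth_damping: float = 0.6
    depths_cm: tuple[float, ...] = (10.0, 20.0, 40.0)
    coldest_doy: int = 15
    start: str = "2019-10-01"
    end: str = "2020-05-01"

    def timestamps(self) -> np.ndarray:
        t = np.arange(
            np.datetime64(self.start, "s"),
            np.datetime64(self.end, "s"),
            np.timedelta64(3, "h"),
        )
        if t.size == 0:
            raise ValueError("zero-length series window")
        return t

    def deterministic_series(self, elevation_m: float, depth_index: int,
                             timestamps: np.ndarray) -> np.ndarray:
        """Noise-free temperature series at one depth for one elevation."""
        doy = _day_of_year(timestamps)
        hour = (timestamps - timestamps.astype("datetime64[D]")) / np.timedelta64(1, "h")
        annual = -self.annual_amplitude_C * np.cos(
            2 * np.pi * (doy - self.coldest_doy) / 365.25
        )
        diurnal = (
            self.diurnal_amplitude_C
            * self.depth_damping**depth_index
            * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
        )
        base = self.ref_mean_C - self.lapse_C_per_km * (elevation_m - self.ref_elevation_m) / 1000.0
        return base + annual + diurnal


def _day_of_year(timestamps: np.ndarray) -> np.ndarray:
    days = timestamps.astype("datetime64[D]")
    years = days.astype("datetime64[Y]")
    return (days - years) / np.timedelta64(1, "D") + 1


@dataclass
class NicheSpec:
    """True niche of a virtual species.

    ``responses`` maps predictor names to (optimum, breadth) of a Gaussian
    bell ``exp(-(x - opt)^2 / (2 breadth^2))``; ``cold_tolerance_days`` is
    the maximum survivable cold-stress frequency (days per winter);
    ``ctmin`` is the species' critical thermal minimum in deg C.
    """

    responses: dict[str, tuple[float, float]]
    cold_tolerance_days: float
    ctmin: float

    def __post_init__(self) -> None:
        for name, (_, breadth) in self.responses.items():
            if breadth <= 0:
                raise ValueError(f"breadth for {name!r} must be positive")
        if self.cold_tolerance_days < 0:
            raise ValueError("cold_tolerance_days must be >= 0")


@dataclass
class TruthSurface:
    """Known truth for a virtual species: suitability and its factors."""

    suitability: Raster
    winter_survival: Raster
    climate_suitability: Raster


def make_landscape(spec: LandscapeSpec, grid: GridDef, seed: int) -> list[Raster]:
    """Generate ``n_climate_vars`` climate surfaces plus elevation.

    Climate surfaces are standardised (zero mean, unit variance over the
    grid) with pairwise correlations approaching ``spec.cross_correlation``
    as the grid grows; elevation carries the north–south trend plus smooth
    relief.  Returned names are ``clim1..climN`` and ``elevation``.
    """
    corr = spec.correlation_matrix()
    rng = np.random.default_rng(seed)
    n = spec.n_climate_vars
    white = rng.standard_normal((n + 1, grid.n_rows, grid.n_cols))
    smooth = ndimage.gaussian_filter(
        white, sigma=(0, spec.spatial_correlation_length, spec.spatial_correlation_length),
        mode="reflect",
    )
    flat = smooth.reshape(n + 1, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)
    # mix to the target cross-correlation via a symmetric matrix square root
    eigval, eigvec = np.linalg.eigh(corr)
    L = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None))) @ eigvec.T
    mixed = L @ flat[:n]
    trend = np.linspace(spec.elev_high_m, spec.elev_low_m, grid.n_rows)[:, None]
    relief = spec.elev_relief_m * flat[n].reshape(grid.shape)
    elevation = trend + relief
    if spec.temp_elevation_corr:
        w = spec.temp_elevation_corr
        if not -1.0 <= w <= 1.0:
            raise ValueError("temp_elevation_corr must lie in [-1, 1]")
        ez = (elevation - elevation.mean()) / elevation.std()
        mixed[0] = w * ez.ravel() + np.sqrt(1.0 - w**2) * mixed[0]
    out = [
        Raster(grid, mixed[i].reshape(grid.shape), f"clim{i + 1}") for i in range(n)
    ]
    out.append(Raster(grid, elevation, "elevation"))
    return out


def make_microclimate(
    grid: GridDef,
    sd_C: float = 3.0,
    correlation_length: float = 8.0,
    seed: int = 0,
) -> Raster:
    """Smooth winter soil-temperature anomaly surface (deg C).

    Represents the microclimatic decoupling of winter soil temperature from
    elevation — snow-cover insulation, exposure, drainage — as a Gaussian
    random field independent of the climate predictors.  It shifts each
    cell's soil-temperature series rigidly, so the true winter-survival
    boundary is not a deterministic function of any traditional predictor:
    the information carried by the physiological variable is genuinely new.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(white, sigma=correlation_length, mode="reflect")
    smooth = (smooth - smooth.mean()) / smooth.std()
    return Raster(grid, sd_C * smooth, "winter_anomaly")


def make_soil_temp_stations(
    elevation: Raster,
    n_stations: int,
    temp_params: TempParams,
    seed: int,
    missing_fraction: float = 0.0,
    anomaly: Raster | None = None,
) -> list[SoilTempSeries]:
    """Place stations uniformly at random on land cells and synthesise series.

    Station spacing is coarser than the predictor grid (stations occupy
    distinct cells of a sparse random subset), mirroring the resolution
    mismatch between meteorological networks and modelling grids.  With
    ``missing_fraction > 0`` each station independently has that probability
    of containing missing readings, exercising the completeness screen.
    """
    if n_stations < 1:
        raise ValueError("n_stations must be >= 1")
    grid = elevation.grid
    rng = np.random.default_rng(seed)
    valid = np.nonzero(elevation.valid_mask.ravel())[0]
    if valid.size < n_stations:
        raise ValueError("fewer valid cells than stations")
    cells = rng.choice(valid, size=n_stations, replace=False)
    rows, cols = np.unravel_index(cells, grid.shape)
    lon, lat = grid.cell_center(rows, cols)
    timestamps = temp_params.timestamps()
    stations = []
    for i in range(n_stations):
        elev = elevation.values[rows[i], cols[i]]
        temps = np.stack(
            [
                temp_params.deterministic_series(elev, d, timestamps)
                for d in range(len(temp_params.depths_cm))
            ]
        )
        if anomaly is not None:
            temps = temps + anomaly.values[rows[i], cols[i]]
        temps = temps + temp_params.noise_sd_C * rng.standard_normal(temps.shape)
        if missing_fraction > 0 and rng.random() < missing_fraction:
            j = rng.integers(0, timestamps.size)
            temps[rng.integers(0, temps.shape[0]), j] = np.nan
        stations.append(
            SoilTempSeries(
                station_id=f"S{i:03d}",
                lon=float(lon[i]),
                lat=float(lat[i]),
                elevation=float(elev),
                depths=list(temp_params.depths_cm),
                timestamps=timestamps,
                temps=temps,
            )
        )
    return stations


def true_stress_frequency(
    elevation: Raster,
    temp_params: TempParams,
    ctmin: float,
    window: OverwinterWindow,
    depth_range: tuple[float, float] = (10.0, 40.0),
    anomaly: Raster | None = None,
) -> Raster:
    """Noise-free cold-stress frequency implied by the temperature model.

    Evaluates the deterministic depth-averaged series per cell elevation
    (plus the microclimate ``anomaly``, if given) and counts days with at
    least one 3-h interval strictly below ``ctmin``.  This is the ground
    truth against which the station-interpolated predictor and the fitted
    models are judged.
    """
    timestamps = temp_params.timestamps()
    mask = window.contains(timestamps)
    if not mask.any():
        raise ValueError("series window does not overlap the overwintering window")
    t = timestamps[mask]
    idx = [
        i for i, d in enumerate(temp_params.depths_cm)
        if depth_range[0] <= d <= depth_range[1]
    ]
    if not idx:
        raise ValueError("no model depth inside depth_range")
    # series for a station at the reference elevation; other elevations are
    # a constant offset, so daily minima shift rigidly with elevation
    prof = np.mean(
        [temp_params.deterministic_series(temp_params.ref_elevation_m, i, t) for i in idx],
        axis=0,
    )
    days = t.astype("datetime64[D]")
    uniq, inverse = np.unique(days, return_inverse=True)
    daily_min = np.full(uniq.size, np.inf)
    np.minimum.at(daily_min, inverse, prof)
    daily_min.sort()
    offset = -temp_params.lapse_C_per_km * (
        elevation.values - temp_params.ref_elevation_m
    ) / 1000.0
    if anomaly is not None:
        offset = offset + anomaly.values
    # day is stressed iff daily_min + offset < ctmin
    counts = np.searchsorted(daily_min, ctmin - offset.ravel(), side="left")
    values = counts.reshape(elevation.grid.shape).astype(float)
    values[~elevation.valid_mask] = elevation.grid.nodata
    return Raster(elevation.grid, values, "cold_stress_frequency_true")


def make_virtual_species(
    climate: list[Raster], stress_freq: Raster, niche: NicheSpec
) -> TruthSurface:
    """Build the true suitability surface of a virtual species.

    Climate suitability is the product of Gaussian bell responses over the
    named predictors, rescaled so its maximum is 1; winter survival is 1
    where the cold-stress frequency does not exceed the tolerance and 0
    elsewhere; true suitability is their elementwise product.
    """
    grid = check_same_grid(*climate, stress_freq)
    by_name = {r.name: r for r in climate}
    clim = np.ones(grid.shape)
    for name, (opt, breadth) in niche.responses.items():
        if name not in by_name:
            raise ValueError(f"niche names unknown predictor {name!r}")
        x = by_name[name].values
        clim = clim * np.exp(-((x - opt) ** 2) / (2.0 * breadth**2))
    peak = clim.max()
    if peak > 0:
        clim = clim / peak
    survival = (stress_freq.values <= niche.cold_tolerance_days).astype(float)
    suit = clim * survival
    return TruthSurface(
        suitability=Raster(grid, suit, "true_suitability"),
        winter_survival=Raster(grid, survival, "winter_survival"),
        climate_suitability=Raster(grid, clim, "climate_suitability"),
    )


def sample_occurrences(
    truth: TruthSurface, n_points: int, seed: int, species_id: str = "virtual"
) -> OccurrenceSet:
    """Draw presence points with cell probability proportional to suitability.

    Each point is placed uniformly within its drawn cell, so occurrences
    behave like field records rather than cell centres.  Cells with zero
    suitability — in particular winter-lethal cells — can never receive a
    point.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    grid = truth.suitability.grid
    p = truth.suitability.values.ravel().astype(float).copy()
    p[~truth.suitability.valid_mask.ravel()] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample occurrences")
    rng = np.random.default_rng(seed)
    cells = rng.choice(p.size, size=n_points, p=p / total)
    rows, cols = np.unravel_index(cells, grid.shape)
    u = rng.random(n_points)
    v = rng.random(n_points)
    lon = grid.west_lon + (cols + u) * grid.cell_size
    lat = grid.north_lat - (rows + v) * grid.cell_size
    df = pd.DataFrame(
        {"species": species_id, "lon": lon, "lat": lat, "source": "synthetic"}
    )
    return OccurrenceSet(df, [f"sampled {n_points} points (seed {seed})"])
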