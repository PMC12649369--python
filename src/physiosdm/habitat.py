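"""Habitat areas, interspecific overlap, and variant difference maps.

Suitability surfaces are binarised at a threshold (the ensemble's
max-TSS threshold by default, a fixed quantile as the alternative), areas
are accumulated in km² with spherical per-row cell areas, and the
climate-only and physiology-informed variants are compared through overlap
ratios, percentage area differences, and categorical reduction/expansion
maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grids import GridDef, Raster, check_same_grid

#: IUGG mean Earth radius, km
EARTH_RADIUS_KM = 6371.0088

#: categorical codes of the variant difference map
DIFF_UNCHANGED_UNSUITABLE = 0
DIFF_UNCHANGED_SUITABLE = 1
DIFF_REDUCTION = 2   # suitable without the physiological constraint only
DIFF_EXPANSION = 3   # suitable with the physiological constraint only

DIFF_CATEGORIES = {
    DIFF_UNCHANGED_UNSUITABLE: "unchanged_unsuitable",
    DIFF_UNCHANGED_SUITABLE: "unchanged_suitable",
    DIFF_REDUCTION: "reduction",
    DIFF_EXPANSION: "expansion",
}


@dataclass
class HabitatSummary:
    """Per-species, per-variant areas and the derived comparison metrics."""

    areas_km2: dict[str, dict[str, float]] = field(default_factory=dict)
    thresholds: dict[str, dict[str, float]] = field(default_factory=dict)
    overlap_km2: dict[str, float] = field(default_factory=dict)
    overlap_ratio_pct: float | None = None
    area_difference_pct: dict[str, float] = field(default_factory=dict)
    difference_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)


def binarize(suitability: Raster, threshold: float) -> Raster:
    """1 where suitability >= threshold, 0 below; nodata preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    vals = np.where(
        suitability.valid_mask,
        (suitability.values >= threshold).astype(float),
        suitability.grid.nodata,
    )
    return Raster(suitability.grid, vals, f"{suitability.name}_binary")


def cell_area_km2(lat_center, cell_size: float) -> np.ndarray:
    """Spherical area of a cell_size x cell_size cell centred at a latitude.

    Area of a lon/lat rectangle on the sphere: R^2 * dlambda * (sin(phi_top)
    - sin(phi_bottom)) with R = 6371.0088 km.
    """
    lat_center = np.asarray(lat_center, dtype=float)
    if np.any(np.abs(lat_center) > 90):
        raise ValueError("latitude outside [-90, 90]")
    half = cell_size / 2.0
    top = np.radians(np.clip(lat_center + half, -90.0, 90.0))
    bot = np.radians(np.clip(lat_center - half, -90.0, 90.0))
    dlon = np.radians(cell_size)
    return EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bot))


def total_area(binary: Raster) -> float:
    """Area (km²) of the 1-cells, weighting each row by its cell-centre
    latitude."""
    vals = binary.values
    valid = binary.valid_mask
    uniq = np.unique(vals[valid])
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"raster is not binary: values {uniq[:5]}")
    row_areas = cell_area_km2(binary.grid.row_center_lats(), binary.grid.cell_size)
    ones_per_row = np.where(valid, vals == 1.0, False).sum(axis=1)
    return float((ones_per_row * row_areas).sum())


def overlap_area(binary_a: Raster, binary_b: Raster) -> float:
    """Area of the elementwise AND of two binary habitat maps (km²)."""
    check_same_grid(binary_a, binary_b)
    both = np.where(
        binary_a.valid_mask & binary_b.valid_mask,
        ((binary_a.values == 1.0) & (binary_b.values == 1.0)).astype(float),
        binary_a.grid.nodata,
    )
    return total_area(Raster(binary_a.grid, both, "overlap"))


def overlap_ratio_pct(overlap_physio_km2: float, overlap_traditional_km2: float) -> float:
    """Physiology-informed overlap as a percentage of the climate-only
    overlap, reported to 2 decimals."""
    if overlap_traditional_km2 <= 0:
        raise ValueError("traditional overlap must be positive")
    return round(100.0 * overlap_physio_km2 / overlap_traditional_km2, 2)


def area_difference_pct(area_traditional_km2: float, area_physio_km2: float) -> float:
    """Percentage by which the climate-only area exceeds the
    physiology-informed area, relative to the latter, to 1 decimal.

    The physiology-informed area is the denominator: the difference is read
    as "how much larger the unconstrained prediction is than the
    constrained one".
    """
    if area_physio_km2 <= 0:
        raise ValueError("physiology-informed area must be positive")
    return round(100.0 * (area_traditional_km2 - area_physio_km2) / area_physio_km2, 1)


def lethal_false_positive_rate(binary: Raster, winter_survival: Raster) -> float:
    """Fraction of winter-lethal cells a binary habitat map calls suitable.

    ``winter_survival`` is the known truth (1 survivable, 0 lethal); the
    rate is predicted-suitable lethal cells over all lethal cells.  Under a
    real winter constraint this is the overestimation a climate-only model
    commits and a physiology-informed model should reduce.
    """
    check_same_grid(binary, winter_survival)
    valid = binary.valid_mask & winter_survival.valid_mask
    lethal = valid & (winter_survival.values == 0.0)
    n_lethal = int(lethal.sum())
    if n_lethal == 0:
        raise ValueError("no winter-lethal cells in the truth surface")
    return float(np.sum(binary.values[lethal] == 1.0) / n_lethal)


def difference_map(
    binary_without: Raster, binary_with: Raster
) -> tuple[Raster, dict[str, int]]:
    """Classify cells by how the physiological constraint changed them.

    Categories: reduction (suitable only without the constraint), expansion
    (suitable only with it), unchanged-suitable, unchanged-unsuitable.
    Returns the categorical raster and the per-category cell counts.
    """
    check_same_grid(binary_without, binary_with)
    valid = binary_without.valid_mask & binary_with.valid_mask
    a = binary_without.values == 1.0
    b = binary_with.values == 1.0
    cat = np.full(binary_without.grid.shape, float(DIFF_UNCHANGED_UNSUITABLE))
    cat[a & b] = DIFF_UNCHANGED_SUITABLE
    cat[a & ~b] = DIFF_REDUCTION
    cat[~a & b] = DIFF_EXPANSION
    cat[~valid] = binary_without.grid.nodata
    counts = {
        name: int(np.sum(cat[valid] == code)) for code, name in DIFF_CATEGORIES.items()
    }
    return Raster(binary_without.grid, cat, "constraint_difference"), counts
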