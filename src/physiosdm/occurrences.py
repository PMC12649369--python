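"""Occurrence records and spatial thinning.

Presence-only records arrive as point tables (species, lon, lat, optional
source).  To limit spatial autocorrelation, records are thinned to at most
one presence per species per grid cell before modelling; the retained count
per species is what enters the train/test splits downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridDef

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("species", "lon", "lat")


@dataclass
class OccurrenceSet:
    """Species-tagged presence points.

    ``records`` holds columns species, lon, lat, source; ``provenance``
    accumulates free-text notes (files read, rows rejected, thinning
    applied).
    """

    records: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records.copy()
        if "source" not in df.columns:
            df["source"] = ""
        df = df[["species", "lon", "lat", "source"]].reset_index(drop=True)
        df["species"] = df["species"].astype(str)
        if (df["species"].str.len() == 0).any():
            raise ValueError("empty species_id in records")
        lon = df["lon"].to_numpy(dtype=float)
        lat = df["lat"].to_numpy(dtype=float)
        bad = ~((lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90))
        if bad.any():
            raise ValueError(
                f"coordinates out of range at rows {np.nonzero(bad)[0][:10].tolist()}"
            )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    def for_species(self, species_id: str) -> "OccurrenceSet":
        sub = self.records[self.records["species"] == species_id]
        return OccurrenceSet(sub, list(self.provenance))

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.records["lon"].to_numpy(dtype=float),
            self.records["lat"].to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class ThinningSummary:
    """Per-species retained counts after thinning."""

    per_species: dict[str, int]
    total: int


def read_occurrences(path) -> OccurrenceSet:
    """Read an occurrence CSV (columns species, lon, lat[, source]).

    Column order is free.  Rows with unparseable or out-of-range coordinates
    are dropped and reported by row number (0-based, data rows); a missing
    required column is a hard error.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file {path} missing required column(s): {missing}")
    notes = [f"read {len(df)} rows from {path}"]
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        lon.notna() & lat.notna()
        & (lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90)
        & df["species"].notna()
    )
    if not ok.all():
        bad_rows = df.index[~ok].tolist()
        logger.warning("%s: rejected %d malformed row(s): %s", path, len(bad_rows), bad_rows)
        notes.append(f"rejected malformed rows: {bad_rows}")
    df = df.loc[ok].copy()
    df["lon"] = lon[ok]
    df["lat"] = lat[ok]
    if df.empty:
        logger.warning("%s: no valid occurrence rows", path)
    return OccurrenceSet(df, notes)


def thin_to_grid(occ: OccurrenceSet, grid: GridDef) -> OccurrenceSet:
    """Retain at most one presence per species per grid cell.

    Thinning is per species: two species sharing a cell each keep a record.
    Within a (species, cell) group the retained record is the first in
    input order after a stable sort by (species, source, input row), so the
    result is deterministic and the operation idempotent.  Points outside
    the grid extent are a hard error.
    """
    df = occ.records
    if df.empty:
        return OccurrenceSet(df.copy(), occ.provenance + ["thinned (empty input)"])
    inside = grid.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
    if not inside.all():
        offenders = df.index[~inside].tolist()
        raise ValueError(f"points outside grid extent at rows {offenders}")
    row, col = grid.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    work = df.assign(_row=row, _col=col, _orig=np.arange(len(df)))
    work = work.sort_values(["species", "source", "_orig"], kind="stable")
    work = work.drop_duplicates(subset=["species", "_row", "_col"], keep="first")
    work = work.sort_values("_orig")  # restore stable input order
    thinned = work[["species", "lon", "lat", "source"]].reset_index(drop=True)
    note = f"thinned {len(df)} -> {len(thinned)} (one per species per cell)"
    return OccurrenceSet(thinned, occ.provenance + [note])


def summarize_counts(occ: OccurrenceSet) -> ThinningSummary:
    """Per-species record counts; the total is their sum."""
    counts = occ.records["species"].value_counts().to_dict()
    counts = {str(k): int(v) for k, v in sorted(counts.items())}
    return ThinningSummary(per_species=counts, total=int(sum(counts.values())))
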