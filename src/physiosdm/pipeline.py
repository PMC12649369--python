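"""End-to-end pipeline: simulate/ingest -> thin -> cold stress -> screen ->
fit -> compare -> report.

:class:`PipelineConfig` holds every tunable of the analysis (grid, species
with their CT_min and winter tolerance, learner list, pseudo-absence and
cross-validation design, retention thresholds, seeds) and
:func:`run_pipeline` executes the stages in order, writing all tables,
rasters and a checksummed manifest to the output directory.  Re-running
with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coldstress, habitat, screening, sdm, synthetic
from .grids import GridDef, Raster, write_ascii_grid
from .occurrences import OccurrenceSet, read_occurrences, summarize_counts, thin_to_grid

logger = logging.getLogger(__name__)

VARIANTS = ("climate_only", "physiology_informed")


@dataclass
class SpeciesConfig:
    """One modelled species: its physiology and (synthetic mode) true niche."""

    species_id: str
    ctmin: float | None = None
    cold_tolerance_days: float = 110.0
    niche_responses: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_occurrences: int = 2000


@dataclass
class PipelineConfig:
    """Full configuration of one analysis run.

    Defaults describe the synthetic desk-scale study: a 100 x 100 grid at
    30 arc-seconds on a high-plateau landscape, two virtual lizard-like
    species with CT_min 0.85 / -1.58 deg C, two learner families, and the
    fixed retention thresholds TSS >= 0.8, AUC >= 0.7, kappa >= 0.6.
    """

    outdir: str = "physiosdm_run"
    seed: int = 0
    # grid
    west_lon: float = 85.0
    north_lat: float = 32.0
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 1.0 / 120.0
    # synthetic world (None paths => simulate)
    occurrences_path: str | None = None
    raster_paths: dict[str, str] | None = None
    station_series_path: str | None = None
    station_meta_path: str | None = None
    n_climate_vars: int = 6
    spatial_correlation_length: float = 8.0
    collinear_pair_rho: float = 0.85
    microclimate_sd_C: float = 3.0
    n_stations: int = 60
    # species
    species: list[SpeciesConfig] = field(default_factory=list)
    variants: tuple[str, ...] = VARIANTS
    # cold stress
    window_year: int = 2019
    year_policy: str = "spanning"
    depth_range: tuple[float, float] = (10.0, 40.0)
    idw_power: float = 2.0
    idw_k: int = 4
    # screening
    collinearity_threshold: float = 0.8
    screen_sample_cells: int = 2000
    # modelling
    learners: tuple[str, ...] = ("logistic", "bagged_trees")
    n_pa_sets: int = 5
    n_per_set: int = 100
    n_cv_reps: int = 4
    train_frac: float = 0.8
    tss_min: float = sdm.RETAIN_TSS_MIN
    auc_min: float = sdm.RETAIN_AUC_MIN
    kappa_min: float = sdm.RETAIN_KAPPA_MIN
    ensemble_weighting: str = "tss"
    compute_importance: bool = True

    def __post_init__(self) -> None:
        if not self.species:
            self.species = default_species()
        self.species = [
            SpeciesConfig(**s) if isinstance(s, dict) else s for s in self.species
        ]
        for name, lo, hi in (
            ("collinearity_threshold", 0.0, 1.0),
            ("tss_min", -1.0, 1.0),
            ("auc_min", 0.0, 1.0),
            ("kappa_min", -1.0, 1.0),
            ("train_frac", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}; choose from {VARIANTS}")
        if "physiology_informed" in self.variants:
            missing = [s.species_id for s in self.species if s.ctmin is None]
            if missing:
                raise ValueError(
                    f"physiology_informed variant requested but species {missing} "
                    "have no ctmin"
                )

    @property
    def grid(self) -> GridDef:
        return GridDef(
            west_lon=self.west_lon,
            north_lat=self.north_lat,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size=self.cell_size,
        )

    @property
    def window(self) -> coldstress.OverwinterWindow:
        return coldstress.OverwinterWindow(self.window_year, self.year_policy)

    def landscape_spec(self) -> synthetic.LandscapeSpec:
        corr = np.eye(self.n_climate_vars)
        if self.n_climate_vars >= 2 and self.collinear_pair_rho:
            # make the last two climate surfaces a collinear pair so the
            # screening stage has real work to do
            i, j = self.n_climate_vars - 2, self.n_climate_vars - 1
            corr[i, j] = corr[j, i] = self.collinear_pair_rho
        return synthetic.LandscapeSpec(
            n_climate_vars=self.n_climate_vars,
            spatial_correlation_length=self.spatial_correlation_length,
            cross_correlation=corr,
        )

    def temp_params(self) -> synthetic.TempParams:
        return synthetic.TempParams(
            start=f"{self.window_year}-10-01",
            end=f"{self.window_year + 1}-05-01"
            if self.year_policy == "spanning"
            else f"{self.window_year}-12-31",
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def default_species() -> list[SpeciesConfig]:
    """Two virtual high-plateau species with contrasting cold physiology.

    Species A tolerates less cold (CT_min 0.85 deg C) than species B
    (CT_min -1.58 deg C), mirroring a lower- vs higher-elevation specialist
    pair; their climate niches overlap partially.
    """
    return [
        SpeciesConfig(
            species_id="species_A",
            ctmin=0.85,
            cold_tolerance_days=110.0,
            niche_responses={"clim1": (0.5, 0.5), "clim2": (0.0, 0.6)},
        ),
        SpeciesConfig(
            species_id="species_B",
            ctmin=-1.58,
            cold_tolerance_days=110.0,
            niche_responses={"clim1": (-0.3, 0.5), "clim3": (0.5, 0.6)},
            n_occurrences=2000,
        ),
    ]


def sum_model_counts(per_learner_counts) -> int:
    """Total ensemble members from per-learner counts (all must be >= 0)."""
    counts = [int(c) for c in (
        per_learner_counts.values() if hasattr(per_learner_counts, "values")
        else per_learner_counts
    )]
    if any(c < 0 for c in counts):
        raise ValueError("negative model count")
    return sum(counts)


@dataclass
class VariantResult:
    """Fitted outcome of one (species, variant) cell."""

    species_id: str
    variant: str
    screen: screening.ScreenReport
    runs: list[sdm.ModelRun]
    retained: list[sdm.ModelRun]
    ensemble: sdm.EnsembleModel
    binary: Raster
    area_km2: float
    contributions: dict[str, float]
    response_curves: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class PipelineResult:
    config: PipelineConfig
    occurrences_raw: OccurrenceSet
    occurrences: OccurrenceSet
    stack_base: list[Raster]
    stress_rasters: dict[str, Raster]
    truths: dict[str, synthetic.TruthSurface]
    variants: dict[tuple[str, str], VariantResult]
    summary: habitat.HabitatSummary
    outdir: Path


def _child_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence((master, *key)).generate_state(1)[0] % (2**31))


def _simulate_inputs(cfg: PipelineConfig):
    grid = cfg.grid
    land = synthetic.make_landscape(cfg.landscape_spec(), grid, _child_seed(cfg.seed, 1))
    climate, elevation = land[:-1], land[-1]
    anomaly = synthetic.make_microclimate(
        grid, cfg.microclimate_sd_C, cfg.spatial_correlation_length,
        _child_seed(cfg.seed, 9),
    )
    stations = synthetic.make_soil_temp_stations(
        elevation, cfg.n_stations, cfg.temp_params(), _child_seed(cfg.seed, 2),
        anomaly=anomaly,
    )
    truths: dict[str, synthetic.TruthSurface] = {}
    occ_frames = []
    for k, sp in enumerate(cfg.species):
        true_stress = synthetic.true_stress_frequency(
            elevation, cfg.temp_params(), sp.ctmin, cfg.window, cfg.depth_range,
            anomaly=anomaly,
        )
        niche = synthetic.NicheSpec(
            responses=sp.niche_responses,
            cold_tolerance_days=sp.cold_tolerance_days,
            ctmin=sp.ctmin,
        )
        truth = synthetic.make_virtual_species(climate, true_stress, niche)
        truths[sp.species_id] = truth
        occ = synthetic.sample_occurrences(
            truth, sp.n_occurrences, _child_seed(cfg.seed, 3, k), sp.species_id
        )
        occ_frames.append(occ.records)
    occurrences = OccurrenceSet(pd.concat(occ_frames, ignore_index=True), ["synthetic"])
    return climate, elevation, stations, truths, occurrences


def _ingest_inputs(cfg: PipelineConfig):
    from .grids import read_ascii_grid

    rasters = {name: read_ascii_grid(p, name) for name, p in cfg.raster_paths.items()}
    elevation = rasters.pop("elevation")
    climate = list(rasters.values())
    series = pd.read_csv(cfg.station_series_path, parse_dates=["timestamp"])
    meta = pd.read_csv(cfg.station_meta_path)
    stations = coldstress.stations_from_frame(series, meta)
    occurrences = read_occurrences(cfg.occurrences_path)
    return climate, elevation, stations, {}, occurrences


def compute_stress_raster(
    stations, window, ctmin, grid, depth_range=(10.0, 40.0), idw_power=2.0, idw_k=4
) -> Raster:
    """Station series -> depth-average -> clip -> complete-station screen ->
    event/day counting -> IDW to the grid.

    The per-station counts remain available as ``raster.station_results``.
    """
    kept = coldstress.drop_incomplete_stations(stations, window, depth_range)
    if not kept:
        raise RuntimeError("no complete station after the completeness screen")
    results = []
    for st in kept:
        prof = coldstress.depth_average(st, depth_range)
        prof = coldstress.clip_window(prof, window)
        results.append(coldstress.count_stress(prof, ctmin, window))
    raster = coldstress.interpolate_to_grid(
        results, grid, idw_power=idw_power, k_neighbors=idw_k
    )
    raster.station_results = results
    return raster


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages and write artifacts + manifest under cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = cfg.grid
    stage = "simulate" if cfg.occurrences_path is None else "ingest"
    try:
        if stage == "simulate":
            climate, elevation, stations, truths, occ_raw = _simulate_inputs(cfg)
        else:
            climate, elevation, stations, truths, occ_raw = _ingest_inputs(cfg)
        logger.info("%s: %d climate vars, %d stations, %d raw records",
                    stage, len(climate), len(stations), len(occ_raw))

        stage = "thin"
        occ = thin_to_grid(occ_raw, grid)
        counts = summarize_counts(occ)
        logger.info("thin: %d -> %d records %s", len(occ_raw), len(occ), counts.per_species)

        stage = "coldstress"
        stress_rasters: dict[str, Raster] = {}
        if "physiology_informed" in cfg.variants:
            for sp in cfg.species:
                stress_rasters[sp.species_id] = compute_stress_raster(
                    stations, cfg.window, sp.ctmin, grid,
                    cfg.depth_range, cfg.idw_power, cfg.idw_k,
                )

        base_stack = list(climate) + [elevation]
        variants: dict[tuple[str, str], VariantResult] = {}
        for sp_index, sp in enumerate(cfg.species):
            occ_sp = occ.for_species(sp.species_id)
            pa_sets = sdm.draw_pseudo_absences(
                grid, occ_sp, cfg.n_pa_sets, cfg.n_per_set,
                seed=_child_seed(cfg.seed, 4, sp_index),
            )
            pa_lon = np.concatenate([p.lon for p in pa_sets])
            pa_lat = np.concatenate([p.lat for p in pa_sets])
            for variant in cfg.variants:
                stage = f"screen[{sp.species_id}/{variant}]"
                stack = list(base_stack)
                if variant == "physiology_informed":
                    stack = stack + [stress_rasters[sp.species_id]]
                rho = screening.spearman_matrix(
                    stack, min(cfg.screen_sample_cells, grid.n_cells),
                    seed=_child_seed(cfg.seed, 5),
                )
                scores = screening.univariate_contribution(
                    stack, occ_sp.coords(), (pa_lon, pa_lat),
                    seed=_child_seed(cfg.seed, 6),
                )
                report = screening.collinearity_filter(
                    rho, scores, [r.name for r in stack], cfg.collinearity_threshold
                )
                kept_stack = [r for r in stack if r.name in report.kept]

                stage = f"fit[{sp.species_id}/{variant}]"
                runs = sdm.fit_all_runs(
                    occ_sp, pa_sets, kept_stack, list(cfg.learners),
                    n_cv_reps=cfg.n_cv_reps, train_frac=cfg.train_frac,
                    seed=_child_seed(cfg.seed, 7),
                )
                retained = sdm.retain_models(
                    runs, cfg.tss_min, cfg.auc_min, cfg.kappa_min
                )
                if not retained:
                    raise RuntimeError(
                        f"no model retained for {sp.species_id}/{variant} at "
                        f"TSS>={cfg.tss_min}, AUC>={cfg.auc_min}, kappa>={cfg.kappa_min}"
                    )
                ens = sdm.build_ensemble(
                    retained, kept_stack, cfg.ensemble_weighting, presences=occ_sp
                )
                contrib = (
                    sdm.variable_importance(ens, kept_stack, seed=_child_seed(cfg.seed, 8))
                    if cfg.compute_importance
                    else {}
                )
                curves = (
                    {name: sdm.response_curve(ens, name) for name in ens.feature_names}
                    if cfg.compute_importance
                    else {}
                )
                binary = habitat.binarize(ens.suitability, ens.metrics.tss_threshold)
                variants[(sp.species_id, variant)] = VariantResult(
                    species_id=sp.species_id,
                    variant=variant,
                    screen=report,
                    runs=runs,
                    retained=retained,
                    ensemble=ens,
                    binary=binary,
                    area_km2=habitat.total_area(binary),
                    contributions=contrib,
                    response_curves=curves,
                )
                logger.info(
                    "fit[%s/%s]: %d/%d runs retained, area %.0f km2",
                    sp.species_id, variant, len(retained), len(runs),
                    variants[(sp.species_id, variant)].area_km2,
                )

        stage = "compare"
        summary = _compare(cfg, variants)

        stage = "report"
        _write_report(cfg, outdir, occ_raw, occ, variants, summary, stress_rasters)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        config=cfg,
        occurrences_raw=occ_raw,
        occurrences=occ,
        stack_base=base_stack,
        stress_rasters=stress_rasters,
        truths=truths,
        variants=variants,
        summary=summary,
        outdir=outdir,
    )


def _compare(cfg: PipelineConfig, variants) -> habitat.HabitatSummary:
    summary = habitat.HabitatSummary()
    for (sp, var), res in variants.items():
        summary.areas_km2.setdefault(sp, {})[var] = res.area_km2
        summary.thresholds.setdefault(sp, {})[var] = res.ensemble.metrics.tss_threshold
    species = [s.species_id for s in cfg.species]
    if len(species) >= 2:
        a, b = species[:2]
        for var in cfg.variants:
            if (a, var) in variants and (b, var) in variants:
                summary.overlap_km2[var] = habitat.overlap_area(
                    variants[(a, var)].binary, variants[(b, var)].binary
                )
        if set(VARIANTS) <= set(summary.overlap_km2):
            trad = summary.overlap_km2["climate_only"]
            phys = summary.overlap_km2["physiology_informed"]
            if trad > 0:
                summary.overlap_ratio_pct = habitat.overlap_ratio_pct(phys, trad)
    for sp in species:
        if all((sp, v) in variants for v in VARIANTS):
            trad = variants[(sp, "climate_only")]
            phys = variants[(sp, "physiology_informed")]
            if phys.area_km2 > 0:
                summary.area_difference_pct[sp] = habitat.area_difference_pct(
                    trad.area_km2, phys.area_km2
                )
            _, counts = habitat.difference_map(trad.binary, phys.binary)
            summary.difference_counts[sp] = counts
    return summary


def _write_report(cfg, outdir: Path, occ_raw, occ, variants, summary, stress_rasters):
    files: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, **kw):
        p = outdir / name
        df.to_csv(p, **kw)
        files.append(p)

    occ.to_csv(outdir / "occurrences_thinned.csv")
    files.append(outdir / "occurrences_thinned.csv")
    counts = summarize_counts(occ)
    save_df(
        pd.DataFrame(
            list(counts.per_species.items()) + [("total", counts.total)],
            columns=["species", "n_records"],
        ),
        "occurrence_counts.csv", index=False,
    )
    metric_rows, member_rows, contrib_rows, curve_rows = [], [], [], []
    for (sp, var), res in variants.items():
        tab = sdm.metrics_table(res.runs)
        tab.columns = ["_".join(c) for c in tab.columns]
        tab.insert(0, "species", sp)
        tab.insert(1, "variant", var)
        metric_rows.append(tab.reset_index())
        for learner, n in sorted(res.ensemble.member_counts_by_learner().items()):
            member_rows.append(
                {"species": sp, "variant": var, "learner": learner, "n_members": n}
            )
        for name, pct in res.contributions.items():
            contrib_rows.append(
                {"species": sp, "variant": var, "variable": name, "contribution_pct": pct}
            )
        for name, curve in res.response_curves.items():
            for _, row in curve.iterrows():
                curve_rows.append(
                    {"species": sp, "variant": var, "variable": name,
                     "value": row[name], "suitability": row["suitability"]}
                )
        res.screen.to_json(outdir / f"screen_{sp}_{var}.json")
        files.append(outdir / f"screen_{sp}_{var}.json")
        write_ascii_grid(res.ensemble.suitability, outdir / f"suitability_{sp}_{var}.asc")
        files.append(outdir / f"suitability_{sp}_{var}.asc")
    save_df(pd.concat(metric_rows, ignore_index=True), "run_metrics.csv", index=False)
    mem = pd.DataFrame(member_rows)
    totals = mem.groupby(["species", "variant"], as_index=False)["n_members"].sum()
    totals["learner"] = "total"
    save_df(pd.concat([mem, totals], ignore_index=True), "member_counts.csv", index=False)
    save_df(pd.DataFrame(contrib_rows), "variable_contributions.csv", index=False)
    if curve_rows:
        save_df(pd.DataFrame(curve_rows), "response_curves.csv", index=False)
    for sp, rast in stress_rasters.items():
        write_ascii_grid(rast, outdir / f"cold_stress_frequency_{sp}.asc")
        files.append(outdir / f"cold_stress_frequency_{sp}.asc")
        station_rows = [
            {
                "station_id": r.station_id, "lon": r.lon, "lat": r.lat,
                "n_events": r.n_events, "n_stress_days": r.n_stress_days,
                "ctmin_C": r.ctmin_used,
            }
            for r in getattr(rast, "station_results", [])
        ]
        if station_rows:
            save_df(pd.DataFrame(station_rows), f"stress_stations_{sp}.csv",
                    index=False)
    summary.to_json(outdir / "habitat_summary.json")
    files.append(outdir / "habitat_summary.json")

    manifest = {
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(files)
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
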