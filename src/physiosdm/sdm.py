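"""Presence/pseudo-absence ensemble suitability modelling.

The modelling design follows the ensemble-platform recipe: pseudo-absence
sets are drawn at random from cells holding no presence of the modelled
species (10 sets of 100 points by default); each set is split 80/20 into
calibration and evaluation data, the split repeated over cross-validation
runs; every learner in a pluggable registry is fitted to every (set, run)
combination; each fitted run is scored on its held-out 20% by AUC,
threshold-maximised TSS and Cohen's kappa; and only runs clearing fixed
thresholds (TSS >= 0.8, AUC >= 0.7, kappa >= 0.6) enter the final ensemble,
a TSS-weighted mean of member predictions.

The registry ships four learner families — penalised logistic regression,
a recursive-partitioning tree, a bagged-tree ensemble (random forest) and
gradient-boosted trees — standing in for the classical GLM/CTA/RF/GBM
quartet; further families plug in through :func:`register_learner`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grids import GridDef, Raster, check_same_grid
from .metrics import THRESHOLD_GRID, MetricSet, evaluate
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

DEFAULT_N_PA_SETS = 10
DEFAULT_N_PER_SET = 100
DEFAULT_N_CV_REPS = 10
DEFAULT_TRAIN_FRAC = 0.8

RETAIN_TSS_MIN = 0.8
RETAIN_AUC_MIN = 0.7
RETAIN_KAPPA_MIN = 0.6


# ---------------------------------------------------------------------------
# learner registry

LEARNER_REGISTRY: dict[str, Callable[[int], object]] = {}


def register_learner(learner_id: str, factory: Callable[[int], object]) -> None:
    """Register a learner family: factory(seed) -> unfitted sklearn-style
    classifier with fit / predict_proba."""
    LEARNER_REGISTRY[learner_id] = factory


# linear + quadratic terms, the classical GLM formulation for unimodal
# (bell-shaped) niche responses
register_learner(
    "logistic",
    lambda seed: make_pipeline(
        StandardScaler(),
        PolynomialFeatures(degree=2, include_bias=False),
        LogisticRegression(max_iter=2000, random_state=seed),
    ),
)
register_learner(
    "tree", lambda seed: DecisionTreeClassifier(max_depth=6, random_state=seed)
)
register_learner(
    "bagged_trees",
    lambda seed: RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
)
register_learner(
    "boosted_trees",
    lambda seed: GradientBoostingClassifier(random_state=seed),
)


def make_learner(learner_id: str, seed: int):
    if learner_id not in LEARNER_REGISTRY:
        raise ValueError(
            f"unknown learner {learner_id!r}; registry: {sorted(LEARNER_REGISTRY)}"
        )
    return LEARNER_REGISTRY[learner_id](seed)


# ---------------------------------------------------------------------------
# domain types

@dataclass
class PASet:
    """One set of pseudo-absence points (distinct presence-free cells)."""

    set_id: str
    lon: np.ndarray
    lat: np.ndarray

    @property
    def n(self) -> int:
        return self.lon.size


@dataclass
class ModelRun:
    """One fitted learner on one pseudo-absence set and CV repetition.

    Holds the fitted estimator (opaque), its held-out evaluation, and the
    held-out data itself so ensembles can re-evaluate against pooled test
    points.
    """

    learner_id: str
    pa_set_id: str
    cv_rep: int
    model: object
    feature_names: list[str]
    metrics: MetricSet
    test_X: np.ndarray
    test_y: np.ndarray
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)[:, 1]


@dataclass
class EnsembleModel:
    """Retained model runs combined into one suitability surface."""

    members: list[ModelRun]
    weights: np.ndarray
    suitability: Raster
    member_count: int
    metrics: MetricSet
    feature_names: list[str]
    presence_means: np.ndarray
    feature_ranges: np.ndarray  # (n_features, 2) observed min/max
    contributions: dict[str, float] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([m.predict(X) for m in self.members])
        return (self.weights[:, None] * preds).sum(axis=0) / self.weights.sum()

    def member_counts_by_learner(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            out[m.learner_id] = out.get(m.learner_id, 0) + 1
        return out


# ---------------------------------------------------------------------------
# operations

def _stack_features(stack: list[Raster], lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    return np.column_stack([r.sample(lon, lat) for r in stack])


def draw_pseudo_absences(
    grid: GridDef,
    presences: OccurrenceSet,
    n_sets: int = DEFAULT_N_PA_SETS,
    n_per_set: int = DEFAULT_N_PER_SET,
    seed: int = 0,
    valid_mask: np.ndarray | None = None,
) -> list[PASet]:
    """Draw random pseudo-absence sets from presence-free cells.

    Within a set, points occupy distinct cells and are placed uniformly
    inside their cell; no point ever falls in a cell containing a presence
    of the modelled species.  Sets are mutually independent given the seed.
    """
    lon_p, lat_p = presences.coords()
    occupied = np.zeros(grid.n_cells, dtype=bool)
    if len(presences):
        row, col = grid.cell_index(lon_p, lat_p)
        occupied[row * grid.n_cols + col] = True
    free = ~occupied
    if valid_mask is not None:
        free &= valid_mask.ravel()
    free_idx = np.nonzero(free)[0]
    if free_idx.size < n_per_set:
        raise ValueError(
            f"only {free_idx.size} presence-free cells available, need {n_per_set}"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for s in range(n_sets):
        cells = rng.choice(free_idx, size=n_per_set, replace=False)
        rows, cols = np.unravel_index(cells, grid.shape)
        u, v = rng.random(n_per_set), rng.random(n_per_set)
        sets.append(
            PASet(
                set_id=f"PA{s + 1:02d}",
                lon=grid.west_lon + (cols + u) * grid.cell_size,
                lat=grid.north_lat - (rows + v) * grid.cell_size,
            )
        )
    return sets


def split_calibration(
    X: np.ndarray,
    y: np.ndarray,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    rep: int = 1,
    seed: int = 0,
):
    """Stratified train/test split; different reps give different partitions.

    Returns (X_train, X_test, y_train, y_test); the union of the parts is
    the input, class ratios are preserved within rounding.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 members to split")
    if counts.min() < 5:
        logger.warning("a class has fewer than 5 members; evaluation will be noisy")
    rs = int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % (2**31))
    return train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=rs
    )


def fit_predict(
    learner_id: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    predict_X: np.ndarray,
    seed: int = 0,
) -> np.ndarray:
    """Fit one learner and score arbitrary feature rows in [0, 1]."""
    model = make_learner(learner_id, seed)
    model.fit(train_X, np.asarray(train_y).astype(int))
    return model.predict_proba(predict_X)[:, 1]


def fit_all_runs(
    presences: OccurrenceSet,
    pa_sets: list[PASet],
    stack: list[Raster],
    learners: list[str],
    n_cv_reps: int = DEFAULT_N_CV_REPS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int = 0,
) -> list[ModelRun]:
    """Fit every learner x pseudo-absence set x CV repetition combination.

    Each run receives an independent seed derived from the master seed and
    its (learner, set, rep) coordinates, so the collection is reproducible
    and order-independent.  Presences are labelled 1, pseudo-absences 0;
    metrics are computed only on the held-out fraction.
    """
    check_same_grid(*stack)
    names = [r.name for r in stack]
    lon_p, lat_p = presences.coords()
    Xp = _stack_features(stack, lon_p, lat_p)
    runs: list[ModelRun] = []
    for li, learner_id in enumerate(sorted(learners)):
        for si, pa in enumerate(pa_sets):
            Xa = _stack_features(stack, pa.lon, pa.lat)
            X = np.vstack([Xp, Xa])
            y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xa))])
            for rep in range(1, n_cv_reps + 1):
                run_seed = int(
                    np.random.SeedSequence((seed, li, si, rep)).generate_state(1)[0]
                    % (2**31)
                )
                Xtr, Xte, ytr, yte = split_calibration(
                    X, y, train_frac=train_frac, rep=rep, seed=run_seed
                )
                model = make_learner(learner_id, run_seed)
                model.fit(Xtr, ytr.astype(int))
                scores = model.predict_proba(Xte)[:, 1]
                runs.append(
                    ModelRun(
                        learner_id=learner_id,
                        pa_set_id=pa.set_id,
                        cv_rep=rep,
                        model=model,
                        feature_names=names,
                        metrics=evaluate(scores, yte.astype(bool)),
                        test_X=Xte,
                        test_y=yte.astype(bool),
                        seed=run_seed,
                    )
                )
    return runs


def retain_models(
    runs: list[ModelRun],
    tss_min: float = RETAIN_TSS_MIN,
    auc_min: float = RETAIN_AUC_MIN,
    kappa_min: float = RETAIN_KAPPA_MIN,
) -> list[ModelRun]:
    """Keep runs meeting all three thresholds (inclusive)."""
    kept = [
        r
        for r in runs
        if r.metrics.tss >= tss_min
        and r.metrics.auc >= auc_min
        and r.metrics.kappa >= kappa_min
    ]
    if not kept:
        logger.warning(
            "no run met TSS>=%.2f, AUC>=%.2f, kappa>=%.2f", tss_min, auc_min, kappa_min
        )
    return kept


def metrics_table(runs: list[ModelRun]) -> pd.DataFrame:
    """Per-learner mean +- SD of kappa / AUC / TSS across runs."""
    rows = [
        {
            "learner": r.learner_id,
            "pa_set": r.pa_set_id,
            "cv_rep": r.cv_rep,
            "kappa": r.metrics.kappa,
            "auc": r.metrics.auc,
            "tss": r.metrics.tss,
        }
        for r in runs
    ]
    df = pd.DataFrame(rows)
    return df.groupby("learner")[["kappa", "auc", "tss"]].agg(["mean", "std"])


def build_ensemble(
    retained: list[ModelRun],
    stack: list[Raster],
    weighting: str = "tss",
    presences: OccurrenceSet | None = None,
) -> EnsembleModel:
    """Combine retained runs into a weighted-mean suitability surface.

    Weights are member TSS values ("tss" mode, the default) or equal
    ("mean" mode).  Ensemble metrics are recomputed by scoring the ensemble
    at every member's held-out points and pooling.  The cellwise ensemble
    value is a convex combination, so it always lies within the member
    prediction range.
    """
    if not retained:
        raise ValueError("cannot build an ensemble from zero retained runs")
    grid = check_same_grid(*stack)
    names = [r.name for r in stack]
    for r in retained:
        if r.feature_names != names:
            raise ValueError("retained runs were fitted on a different stack")
    if weighting == "tss":
        weights = np.array([max(r.metrics.tss, 1e-9) for r in retained])
    elif weighting == "mean":
        weights = np.ones(len(retained))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    valid = np.logical_and.reduce([r.valid_mask for r in stack])
    Xcells = np.column_stack([r.values[valid] for r in stack])
    acc = np.zeros(len(Xcells))
    for w, m in zip(weights, retained):
        acc += w * m.predict(Xcells)
    surface = np.full(grid.shape, grid.nodata)
    surface[valid] = acc / weights.sum()
    suit = Raster(grid, surface, "ensemble_suitability")

    pooled_X = np.vstack([m.test_X for m in retained])
    pooled_labels = np.concatenate([m.test_y for m in retained])
    preds = np.stack([m.predict(pooled_X) for m in retained])
    pooled_scores = (weights[:, None] * preds).sum(axis=0) / weights.sum()
    ens_metrics = evaluate(pooled_scores, pooled_labels)

    if presences is not None and len(presences):
        lon_p, lat_p = presences.coords()
        pres_means = _stack_features(stack, lon_p, lat_p).mean(axis=0)
    else:
        pres_means = Xcells.mean(axis=0)
    ranges = np.column_stack([Xcells.min(axis=0), Xcells.max(axis=0)])
    return EnsembleModel(
        members=list(retained),
        weights=weights,
        suitability=suit,
        member_count=len(retained),
        metrics=ens_metrics,
        feature_names=names,
        presence_means=pres_means,
        feature_ranges=ranges,
    )


def variable_importance(
    ensemble: EnsembleModel,
    stack: list[Raster],
    n_perm: int = 3,
    seed: int = 0,
    max_cells: int = 2000,
) -> dict[str, float]:
    """Permutation contribution of each predictor, as percentages.

    The raw importance of a variable is 1 minus the Pearson correlation
    between the ensemble prediction and the prediction with that variable's
    column permuted, averaged over ``n_perm`` permutations; raw values are
    normalised to sum to 100.  A variable the ensemble ignores scores ~0.
    """
    grid = check_same_grid(*stack)
    if [r.name for r in stack] != ensemble.feature_names:
        raise ValueError("stack does not match ensemble features")
    valid = np.logical_and.reduce([r.valid_mask for r in stack])
    X = np.column_stack([r.values[valid] for r in stack])
    rng = np.random.default_rng(seed)
    if len(X) > max_cells:
        X = X[rng.choice(len(X), size=max_cells, replace=False)]
    base = ensemble.predict(X)
    if np.ptp(base) == 0:
        logger.warning("constant ensemble prediction; importances undefined, all zero")
        return {n: 0.0 for n in ensemble.feature_names}
    raw = np.zeros(len(ensemble.feature_names))
    for j in range(len(ensemble.feature_names)):
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            pred = ensemble.predict(Xp)
            if np.ptp(pred) == 0:
                r = 0.0
            else:
                r = np.corrcoef(base, pred)[0, 1]
            raw[j] += max(0.0, 1.0 - r)
    raw /= n_perm
    total = raw.sum()
    if total == 0:
        return {n: 0.0 for n in ensemble.feature_names}
    pct = 100.0 * raw / total
    return dict(zip(ensemble.feature_names, pct))


def response_curve(
    ensemble: EnsembleModel, variable: str, n_steps: int = 50
) -> pd.DataFrame:
    """Marginal response of ensemble suitability to one predictor.

    All other predictors are held at their presence-cell means while the
    target variable sweeps ``n_steps`` equally spaced values across its
    observed range (the evaluation-strip convention).
    """
    if variable not in ensemble.feature_names:
        raise ValueError(
            f"unknown variable {variable!r}; ensemble uses {ensemble.feature_names}"
        )
    j = ensemble.feature_names.index(variable)
    lo, hi = ensemble.feature_ranges[j]
    values = np.linspace(lo, hi, n_steps)
    X = np.tile(ensemble.presence_means, (n_steps, 1))
    X[:, j] = values
    return pd.DataFrame({variable: values, "suitability": ensemble.predict(X)})
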