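"""Collinearity screening of the predictor stack.

Candidate predictors are screened pairwise by Spearman rank correlation on
a common random sample of valid cells; whenever two predictors are highly
correlated (|rho| at or above the threshold, 0.8 by default) the member
with the lower contribution score is dropped.  The contribution proxy is
the cross-validated discrimination (rank AUC) of a single-variable
quadratic-logistic learner against the presence/pseudo-absence labels —
label-aware, cheap, and able to credit unimodal (bell-shaped) responses
that a purely linear score would miss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grids import Raster, check_same_grid
from .metrics import roc_auc

logger = logging.getLogger(__name__)

DEFAULT_COLLINEARITY_THRESHOLD = 0.8


@dataclass
class ScreenReport:
    """Outcome of the collinearity filter.

    ``dropped`` lists (dropped_name, kept_name, rho) triples in elimination
    order; kept + dropped names partition the input variables, and no kept
    pair reaches the threshold.
    """

    names: list[str]
    matrix: np.ndarray
    scores: dict[str, float]
    threshold: float
    kept: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str, float]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "names": self.names,
            "threshold": self.threshold,
            "spearman": self.matrix.tolist(),
            "contribution_scores": self.scores,
            "kept": self.kept,
            "dropped": [
                {"dropped": d, "kept_instead": k, "rho": r} for d, k, r in self.dropped
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def spearman_matrix(
    stack: list[Raster], sample_cells: int | None = None, seed: int = 0
) -> np.ndarray:
    """Pairwise Spearman rho over a common random sample of valid cells.

    A constant variable has undefined rank correlation; its entries are set
    to 0 with a warning so it can never trigger an elimination.
    """
    if len(stack) < 2:
        raise ValueError("need at least two variables")
    check_same_grid(*stack)
    valid = np.logical_and.reduce([r.valid_mask for r in stack]).ravel()
    idx = np.nonzero(valid)[0]
    if sample_cells is not None:
        if sample_cells > idx.size:
            raise ValueError(f"sample_cells {sample_cells} exceeds {idx.size} valid cells")
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=sample_cells, replace=False)
    data = np.column_stack([r.values.ravel()[idx] for r in stack])
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(data).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-variable case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    if np.isnan(rho).any():
        const = [stack[i].name for i in range(len(stack)) if np.ptp(data[:, i]) == 0]
        logger.warning("constant variable(s) %s: correlations undefined, set to 0", const)
        rho = np.where(np.isnan(rho), 0.0, rho)
    np.fill_diagonal(rho, 1.0)
    return rho


def univariate_contribution(
    stack: list[Raster],
    presence_lonlat: tuple[np.ndarray, np.ndarray],
    absence_lonlat: tuple[np.ndarray, np.ndarray],
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Per-variable contribution proxy: cross-validated single-variable AUC.

    Each variable is fit alone (with a quadratic term, so unimodal responses
    score well) in a logistic model under stratified K-fold CV; the score is
    the rank AUC of pooled out-of-fold predictions.  A pure-noise variable
    scores near 0.5, a perfectly informative one near 1.
    """
    check_same_grid(*stack)
    X_parts, y_parts = [], []
    for (lon, lat), label in ((presence_lonlat, 1), (absence_lonlat, 0)):
        vals = np.column_stack([r.sample(lon, lat) for r in stack])
        X_parts.append(vals)
        y_parts.append(np.full(len(lon), label))
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: need presences and absences")
    scores: dict[str, float] = {}
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for j, rast in enumerate(stack):
        x = X[:, j]
        feats = np.column_stack([x, x**2])
        oof = np.empty(len(y))
        for tr, te in cv.split(feats, y):
            model = make_pipeline(
                StandardScaler(), LogisticRegression(max_iter=1000)
            )
            model.fit(feats[tr], y[tr])
            oof[te] = model.predict_proba(feats[te])[:, 1]
        scores[rast.name] = roc_auc(oof, y)
    return scores


def collinearity_filter(
    matrix: np.ndarray,
    scores: dict[str, float],
    names: list[str] | None = None,
    threshold: float = DEFAULT_COLLINEARITY_THRESHOLD,
) -> ScreenReport:
    """Greedy highest-correlation-first elimination.

    Repeatedly find the kept pair with the largest |rho| at or above the
    threshold and drop its lower-scoring member (score ties drop the later
    name in the stable input ordering) until no kept pair reaches the
    threshold.  Deterministic given (matrix, scores, ordering).
    """
    matrix = np.asarray(matrix, dtype=float)
    if names is None:
        names = list(scores.keys())
    if matrix.shape != (len(names), len(names)):
        raise ValueError("matrix shape does not match variable names")
    if set(names) - set(scores):
        raise ValueError(f"missing contribution scores for {sorted(set(names) - set(scores))}")
    report = ScreenReport(
        names=list(names), matrix=matrix, scores=dict(scores), threshold=threshold
    )
    alive = list(range(len(names)))
    dropped: list[tuple[str, str, float]] = []
    while True:
        best_pair, best_abs = None, threshold
        for ai, i in enumerate(alive):
            for j in alive[ai + 1:]:
                a = abs(matrix[i, j])
                if a >= best_abs and (best_pair is None or a > best_abs):
                    best_pair, best_abs = (i, j), a
        if best_pair is None:
            break
        i, j = best_pair
        si, sj = scores[names[i]], scores[names[j]]
        # drop the lower-scoring member; on a tie the later in input order
        loser, winner = (i, j) if si < sj else (j, i)
        dropped.append((names[loser], names[winner], float(matrix[i, j])))
        alive.remove(loser)
    report.kept = [names[i] for i in alive]
    report.dropped = dropped
    return report
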