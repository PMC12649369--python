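"""Discrimination metrics for presence/absence scores.

AUC is computed in its rank formulation (probability a random presence
outscores a random absence, ties counted one half).  TSS and Cohen's kappa
are threshold-dependent and are reported at their maximum over a fixed grid
of 101 thresholds 0.00–1.00, the convention of ensemble SDM platforms; the
smallest maximising threshold is reported on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: threshold grid for TSS / kappa maximisation
THRESHOLD_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class MetricSet:
    """Held-out evaluation of one model: AUC, max-TSS, max-kappa."""

    auc: float
    tss: float
    tss_threshold: float
    kappa: float
    kappa_threshold: float


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to evaluate")
    return labels, ~labels


def roc_auc(scores, labels) -> float:
    """Rank-based AUC: P(score_presence > score_absence), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    ranks = stats.rankdata(scores)  # average ranks handle ties
    n_pos, n_neg = pos.sum(), neg.sum()
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _confusion_curves(scores: np.ndarray, labels: np.ndarray, grid: np.ndarray):
    """Vectorised confusion counts (tp, fp, fn, tn) over a threshold grid.

    Predicted presence iff score >= threshold.
    """
    pos, neg = _check_two_classes(labels)
    pred = scores[None, :] >= grid[:, None]
    tp = (pred & pos[None, :]).sum(axis=1).astype(float)
    fp = (pred & neg[None, :]).sum(axis=1).astype(float)
    fn = pos.sum() - tp
    tn = neg.sum() - fp
    return tp, fp, fn, tn


def max_tss(scores, labels, threshold_grid: np.ndarray = THRESHOLD_GRID) -> tuple[float, float]:
    """Maximum true skill statistic (sensitivity + specificity - 1) and the
    smallest threshold attaining it."""
    scores = np.asarray(scores, dtype=float)
    grid = np.asarray(threshold_grid, dtype=float)
    tp, fp, fn, tn = _confusion_curves(scores, labels, grid)
    tss = tp / (tp + fn) + tn / (tn + fp) - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (smallest) maximiser
    return float(tss[best]), float(grid[best])


def max_kappa(scores, labels, threshold_grid: np.ndarray = THRESHOLD_GRID) -> tuple[float, float]:
    """Maximum Cohen's kappa (p_o - p_e)/(1 - p_e) over the threshold grid."""
    scores = np.asarray(scores, dtype=float)
    grid = np.asarray(threshold_grid, dtype=float)
    tp, fp, fn, tn = _confusion_curves(scores, labels, grid)
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.where(pe < 1.0, (po - pe) / (1.0 - pe), 0.0)
    best = int(np.argmax(kappa))
    return float(kappa[best]), float(grid[best])


def evaluate(scores, labels, threshold_grid: np.ndarray = THRESHOLD_GRID) -> MetricSet:
    """All three metrics on one held-out score/label set."""
    auc = roc_auc(scores, labels)
    tss, tss_thr = max_tss(scores, labels, threshold_grid)
    kappa, kappa_thr = max_kappa(scores, labels, threshold_grid)
    return MetricSet(auc=auc, tss=tss, tss_threshold=tss_thr,
                     kappa=kappa, kappa_threshold=kappa_thr)
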