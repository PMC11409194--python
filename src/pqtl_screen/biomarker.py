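"""Validation-phase biomarker statistics: group comparison and ROC/AUC.

AUC is computed by the Mann-Whitney rank formula with midrank tie
handling (identical to trapezoidal integration of the empirical ROC
curve); confidence intervals come from a seeded stratified percentile
bootstrap. Combined markers are scored by an in-sample logistic fit.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .association import logistic_fit
from .datatypes import RocResult
from .exceptions import SeparationError, ValidationError

logger = logging.getLogger(__name__)


def group_compare(levels: np.ndarray, status: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test of marker levels, case vs control.

    Returns (mean difference case - control, t statistic, two-sided p).
    Zero pooled variance with equal means yields p = 1.
    """
    levels = np.asarray(levels, dtype=float)
    status = np.asarray(status)
    x, y = levels[status == 1], levels[status == 0]
    if x.size < 2 or y.size < 2:
        raise ValidationError("need >= 2 samples per group")
    diff = x.mean() - y.mean()
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0.0:
        if diff == 0.0:
            logger.warning("degenerate comparison: zero variance, equal means; p = 1")
            return 0.0, 0.0, 1.0
        return float(diff), float(np.sign(diff) * np.inf), 0.0
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)
    return float(diff), float(t), float(p)


def _auc_rank(scores: np.ndarray, status: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks: P(case score > control score) + ties/2."""
    n1 = int((status == 1).sum())
    n0 = int((status == 0).sum())
    ranks = stats.rankdata(scores)  # midranks
    r1 = ranks[status == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_mann_whitney(
    scores: np.ndarray,
    status: np.ndarray,
    direction: str = "auto",
    marker: str = "marker",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> RocResult:
    """AUC of a single marker with stratified percentile-bootstrap 95% CI.

    ``direction``: 'higher_in_cases' uses the scores as-is,
    'lower_in_cases' negates them, 'auto' orients so AUC >= 0.5 and
    records the chosen orientation.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status).astype(int)
    if (status == 1).sum() == 0 or (status == 0).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    if direction not in ("higher_in_cases", "lower_in_cases", "auto"):
        raise ValidationError(f"unknown direction {direction!r}")
    oriented = scores
    orientation = "higher_in_cases"
    if direction == "lower_in_cases":
        oriented = -scores
        orientation = "lower_in_cases"
    elif direction == "auto":
        if _auc_rank(scores, status) < 0.5:
            oriented = -scores
            orientation = "lower_in_cases"
    auc = _auc_rank(oriented, status)

    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(case_idx, size=case_idx.size, replace=True)
        ki = rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True)
        idx = np.concatenate([ci, ki])
        boots[b] = _auc_rank(oriented[idx], status[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(
        marker=marker,
        auc=auc,
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
        n_cases=int(case_idx.size),
        n_controls=int(ctrl_idx.size),
        orientation=orientation,
    )


def combined_score(
    level_matrix: np.ndarray,
    status: np.ndarray,
    marker_names: Optional[list[str]] = None,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> RocResult:
    """ROC of the in-sample logistic combination of several markers.

    ``level_matrix`` is markers x samples. The score is the linear
    predictor of a logistic regression of status on the markers; under
    separation the score falls back to an equal-weight standardized sum
    (flagged in the marker name).
    """
    levels = np.atleast_2d(np.asarray(level_matrix, dtype=float))
    status = np.asarray(status).astype(int)
    if np.isnan(levels).any():
        raise ValidationError("missing marker values not supported")
    name = "combined"
    X = np.column_stack([np.ones(levels.shape[1]), levels.T])
    try:
        fit = logistic_fit(X, status.astype(float))
        score = X @ fit.coef
    except SeparationError:
        logger.warning("separation in combined fit; equal-weight standardized sum used")
        z = (levels - levels.mean(axis=1, keepdims=True)) / levels.std(axis=1, keepdims=True, ddof=1)
        score = z.sum(axis=0)
        name = "combined(equal_weight_fallback)"
    return auc_mann_whitney(score, status, direction="auto", marker=name,
                            n_boot=n_boot, seed=seed)


def roc_points(scores: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve points (FPR, TPR, threshold) for plotting/output."""
    fpr, tpr, thr = roc_curve(np.asarray(status).astype(int), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def roc_results_frame(results: list[RocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [r.marker for r in results],
            "auc": [r.auc for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "n_cases": [r.n_cases for r in results],
            "n_controls": [r.n_controls for r in results],
            "orientation": [r.orientation for r in results],
        }
    )
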