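"""Differential protein expression and cross-compartment intersection.

Plasma uses an unpaired pooled-variance (Student's) two-sample t-test per
protein; tissue uses a paired t-test on tumor - adjacent differences.
Proteins significant in both compartments with the same direction are
retained and role-labelled: 'suppressor' when lower in cases/tumors,
'oncogenic' when higher. No multiple-testing correction is applied at
this screening stage (raw p < alpha), by design; downstream stages treat
the labels as hypotheses, not confirmed biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ProteinMatrix
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEResult:
    """Per-protein differential-expression test result."""

    protein_id: str
    log2_fc: float  # mean difference: case - control, or tumor - adjacent
    t_stat: float
    p_value: float
    direction: str  # up | down | flat


def normalize(matrix: ProteinMatrix, method: str = "log2_median_center") -> ProteinMatrix:
    """Normalize a protein matrix.

    ``log2_median_center``: log2-transform raw abundances then subtract
    each sample's median (every column ends with median 0).
    ``median_center``: same centering for values already on the log2 scale.
    ``none``: identity.
    """
    if method == "none":
        return matrix
    values = matrix.values
    if method == "log2_median_center":
        if matrix.is_log2:
            raise ValidationError("matrix is already log2; use method='median_center'")
        bad = np.argwhere(values <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-positive abundance at protein {matrix.protein_ids[i]!r}, "
                f"sample {matrix.sample_ids[j]!r}"
            )
        values = np.log2(values)
    elif method != "median_center":
        raise ValidationError(f"unknown normalization method {method!r}")
    centered = values - np.median(values, axis=0, keepdims=True)
    return matrix.copy_with(values=centered, is_log2=True)


def _direction(log2_fc: float, p: float, alpha: float) -> str:
    if p < alpha and log2_fc > 0:
        return "up"
    if p < alpha and log2_fc < 0:
        return "down"
    return "flat"


def de_test_unpaired(matrix: ProteinMatrix, alpha: float = 0.05) -> list[DEResult]:
    """Pooled-variance two-sample t-test per protein, case vs control.

    Degenerate proteins (zero pooled variance, equal means) get t = 0 and
    p = 1 with a logged warning so null fixtures run cleanly.
    """
    groups = set(matrix.group)
    if groups != {"case", "control"}:
        raise ValidationError(f"expected case/control labels, got {sorted(groups)}")
    g = np.asarray(matrix.group)
    x = matrix.values[:, g == "case"]
    y = matrix.values[:, g == "control"]
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 samples per group")
    diff = x.mean(axis=1) - y.mean(axis=1)
    sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    return _finish_t(matrix.protein_ids, diff, se, df, alpha)


def de_test_paired(matrix: ProteinMatrix, alpha: float = 0.05) -> list[DEResult]:
    """Paired t-test per protein on tumor - adjacent differences."""
    if matrix.pair_id is None:
        raise ValidationError("paired test requires pair_id metadata")
    g = np.asarray(matrix.group)
    pid = np.asarray(matrix.pair_id)
    pairs = pd.unique(pid)
    tumor_col, adj_col = {}, {}
    for j, (p, grp) in enumerate(zip(pid, g)):
        (tumor_col if grp == "tumor" else adj_col).setdefault(p, []).append(j)
    bad = [p for p in pairs if len(tumor_col.get(p, [])) != 1 or len(adj_col.get(p, [])) != 1]
    if bad:
        raise ValidationError(f"pairs without exactly one tumor and one adjacent column: {bad}")
    if len(pairs) < 2:
        raise ValidationError("need >= 2 pairs")
    t_idx = [tumor_col[p][0] for p in pairs]
    a_idx = [adj_col[p][0] for p in pairs]
    d = matrix.values[:, t_idx] - matrix.values[:, a_idx]
    n = len(pairs)
    diff = d.mean(axis=1)
    se = d.std(axis=1, ddof=1) / np.sqrt(n)
    return _finish_t(matrix.protein_ids, diff, se, n - 1, alpha)


def _finish_t(
    protein_ids: list[str], diff: np.ndarray, se: np.ndarray, df: int, alpha: float
) -> list[DEResult]:
    results = []
    for pid, d, s in zip(protein_ids, diff, se):
        if s == 0.0:
            if d == 0.0:
                logger.warning("protein %s: zero variance and equal means; p set to 1", pid)
                t, p = 0.0, 1.0
            else:
                t = np.inf if d > 0 else -np.inf
                p = 0.0
        else:
            t = d / s
            p = 2.0 * stats.t.sf(abs(t), df)
        results.append(DEResult(pid, float(d), float(t), float(p), _direction(d, p, alpha)))
    return results


def intersect_consistent(
    plasma: list[DEResult], tissue: list[DEResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Intersect compartments requiring joint significance and matching direction.

    Returns one row per retained protein with its role label
    ('suppressor' when down in both compartments, 'oncogenic' when up)
    plus the per-compartment statistics. Empty intersection is valid.
    """
    t_by_id = {r.protein_id: r for r in tissue}
    rows = []
    for rp in plasma:
        rt = t_by_id.get(rp.protein_id)
        if rt is None:
            continue
        if rp.p_value < alpha and rt.p_value < alpha and rp.direction == rt.direction \
                and rp.direction != "flat":
            rows.append(
                {
                    "protein_id": rp.protein_id,
                    "role": "oncogenic" if rp.direction == "up" else "suppressor",
                    "plasma_log2_fc": rp.log2_fc,
                    "plasma_p": rp.p_value,
                    "tissue_log2_fc": rt.log2_fc,
                    "tissue_p": rt.p_value,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "role", "plasma_log2_fc", "plasma_p",
            "tissue_log2_fc", "tissue_p",
        ],
    )
    n_up = int((out["role"] == "oncogenic").sum())
    n_down = int((out["role"] == "suppressor").sum())
    logger.info("intersection: %d proteins (%d up, %d down)", len(out), n_up, n_down)
    return out


def de_results_frame(results: list[DEResult], compartment: str) -> pd.DataFrame:
    """Tabulate DE results for TSV output."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "compartment": compartment,
            "log2_fc": [r.log2_fc for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )
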