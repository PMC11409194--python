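"""Case-control association under codominant, dominant, recessive and
additive genetic models.

Crude odds ratios come from contingency-table cross-products with Wald
confidence intervals on the log scale and a Haldane-Anscombe +0.5
correction when any contrast cell is empty. Adjusted analyses use a
maximum-likelihood logistic regression fitted by iteratively reweighted
least squares (IRLS), with standard errors from the inverse observed
information; for a saturated 2x2 design the logistic coefficient equals
the log crude OR exactly, which the test suite asserts to 10 significant
digits against an independent fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .datatypes import MISSING, AssocResult, ContingencyTable, GenotypeData
from .exceptions import SeparationError, ValidationError

logger = logging.getLogger(__name__)

MODELS = ("het_vs_ref", "hom_vs_ref", "dominant", "recessive", "additive")
Z95 = stats.norm.ppf(0.975)


def genotype_counts(genotypes: GenotypeData) -> list[ContingencyTable]:
    """Per-SNP genotype x case/control counts; missing calls tallied and excluded."""
    if genotypes.status is None:
        raise ValidationError("genotype_counts requires phenotype status")
    status = genotypes.status
    tables = []
    for i, snp in enumerate(genotypes.snp_ids):
        row = genotypes.dosages[i]
        miss = row == MISSING
        if miss.all():
            logger.warning("%s: all genotypes missing; excluded", snp)
            continue
        cases = tuple(int(((row == g) & (status == 1)).sum()) for g in (0, 1, 2))
        ctrls = tuple(int(((row == g) & (status == 0)).sum()) for g in (0, 1, 2))
        tables.append(ContingencyTable(snp, cases, ctrls, n_missing=int(miss.sum())))
    return tables


def _contrast_cells(table: ContingencyTable, model: str) -> tuple[float, float, float, float]:
    """(exposed-case, exposed-control, unexposed-case, unexposed-control)."""
    c0, c1, c2 = table.cases
    k0, k1, k2 = table.controls
    if model == "het_vs_ref":
        return c1, k1, c0, k0
    if model == "hom_vs_ref":
        return c2, k2, c0, k0
    if model == "dominant":
        return c1 + c2, k1 + k2, c0, k0
    if model == "recessive":
        return c2, k2, c0 + c1, k0 + k1
    raise ValidationError(f"crude_or does not support model {model!r}")


def crude_or(table: ContingencyTable, model: str) -> AssocResult:
    """Cross-product odds ratio with 95% Wald CI and two-sided Wald p.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).
    A zero cell triggers the Haldane-Anscombe +0.5 correction on all four
    cells and flags the result.
    """
    a, b, c, d = _contrast_cells(table, model)
    corrected = False
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_est = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    log_or = float(np.log(or_est))
    z = log_or / se
    return AssocResult(
        snp_id=table.snp_id,
        model=model,
        or_estimate=float(or_est),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        adjusted=False,
        n_case_exposed=int(a) if not corrected else None,
        n_control_exposed=int(b) if not corrected else None,
        continuity_corrected=corrected,
    )


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic-regression fit."""

    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    cov: np.ndarray
    n_iter: int
    converged: bool


def logistic_fit(
    design: np.ndarray,
    outcome: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 15.0,
) -> LogisticFit:
    """Fit logistic regression by IRLS.

    ``design`` must include the intercept column and be full rank.
    Convergence: gradient max-norm < ``tol`` within ``max_iter``
    iterations. A coefficient diverging past ``separation_bound`` in
    absolute value raises :class:`SeparationError`.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValidationError("design must be 2-D with one outcome per row")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    beta = np.zeros(X.shape[1])
    converged = False
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        if np.abs(beta).max() > separation_bound:
            raise SeparationError(
                "coefficient diverged past "
                f"{separation_bound}; data are (quasi-)separated"
            )
        if np.abs(grad).max() < tol:
            converged = True
            break
    p = expit(X @ beta)
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    return LogisticFit(
        coef=beta,
        se=se,
        p_values=2.0 * stats.norm.sf(np.abs(z)),
        cov=cov,
        n_iter=it,
        converged=converged,
    )


def _model_columns(dosage: np.ndarray, model: str) -> np.ndarray:
    """Genotype encoding columns for one model (samples x k)."""
    g = dosage.astype(float)
    if model == "codominant":
        return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    if model == "dominant":
        return (g >= 1).astype(float)[:, None]
    if model == "recessive":
        return (g == 2).astype(float)[:, None]
    if model == "additive":
        return g[:, None]
    raise ValidationError(f"unknown model {model!r}")


def _wald_result(
    snp_id: str,
    model: str,
    fit: LogisticFit,
    idx: int,
    adjusted: bool,
    covariates: tuple[str, ...],
    n_case_exposed: Optional[int],
    n_control_exposed: Optional[int],
) -> AssocResult:
    log_or, se = float(fit.coef[idx]), float(fit.se[idx])
    return AssocResult(
        snp_id=snp_id,
        model=model,
        or_estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        p_value=float(fit.p_values[idx]),
        adjusted=adjusted,
        covariates=covariates,
        n_case_exposed=n_case_exposed,
        n_control_exposed=n_control_exposed,
    )


def association_scan(
    genotypes: GenotypeData,
    models: Sequence[str] = MODELS,
    adjust: Sequence[str] = (),
    alpha: float = 0.05,
) -> tuple[list[AssocResult], dict[str, bool]]:
    """Fit all requested genetic models per SNP by logistic regression.

    het_vs_ref/hom_vs_ref come from one codominant fit with two genotype
    dummies; dominant, recessive and additive are separate fits. Samples
    with a missing call are dropped per SNP. ``adjust`` may name
    'age_group'. The per-SNP significance flag is additive-model
    p < alpha. Per-SNP fit failures (separation, rank deficiency) are
    logged and skipped without aborting the scan.
    """
    if genotypes.status is None:
        raise ValidationError("association_scan requires phenotype status")
    covariate_cols = []
    for name in adjust:
        arr = getattr(genotypes, name, None)
        if arr is None:
            raise ValidationError(f"covariate {name!r} not present")
        covariate_cols.append(np.asarray(arr, dtype=float))
    models = list(models)
    bad = set(models) - set(MODELS)
    if bad:
        raise ValidationError(f"unknown models: {sorted(bad)}")
    want_codominant = bool({"het_vs_ref", "hom_vs_ref"} & set(models))
    fit_models = [m for m in models if m in ("dominant", "recessive", "additive")]

    results: list[AssocResult] = []
    flags: dict[str, bool] = {}
    y_all = genotypes.status.astype(float)
    for i, snp in enumerate(genotypes.snp_ids):
        row = genotypes.dosages[i]
        ok = row != MISSING
        g, y = row[ok].astype(float), y_all[ok]
        covs = [c[ok] for c in covariate_cols]
        n1 = np.column_stack([np.ones_like(y)] + covs)
        try:
            if want_codominant:
                cols = _model_columns(g, "codominant")
                fit = logistic_fit(np.hstack([n1, cols]), y)
                k = n1.shape[1]
                if "het_vs_ref" in models:
                    results.append(
                        _wald_result(snp, "het_vs_ref", fit, k, bool(adjust), tuple(adjust),
                                     int(((g == 1) & (y == 1)).sum()), int(((g == 1) & (y == 0)).sum()))
                    )
                if "hom_vs_ref" in models:
                    results.append(
                        _wald_result(snp, "hom_vs_ref", fit, k + 1, bool(adjust), tuple(adjust),
                                     int(((g == 2) & (y == 1)).sum()), int(((g == 2) & (y == 0)).sum()))
                    )
            for model in fit_models:
                cols = _model_columns(g, model)
                fit = logistic_fit(np.hstack([n1, cols]), y)
                exposed = cols[:, 0] if model != "additive" else (g >= 1).astype(float)
                res = _wald_result(snp, model, fit, n1.shape[1], bool(adjust), tuple(adjust),
                                   int(((exposed > 0) & (y == 1)).sum()),
                                   int(((exposed > 0) & (y == 0)).sum()))
                results.append(res)
                if model == "additive":
                    flags[snp] = res.p_value < alpha
        except (SeparationError, ValidationError) as exc:
            logger.warning("%s: fit failed (%s); SNP skipped", snp, exc)
            continue
    return results, flags


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (emitted for transparency, not selection)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
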