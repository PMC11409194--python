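"""Regulation-pattern concordance: select biologically plausible pQTL-SNPs.

A variant is 'plausible' when the sign of its protein effect (beta), the
protein's role, and its disease odds-ratio direction tell one coherent
story: lowering a tumor-suppressor (or raising an oncogenic protein)
should raise risk (OR > 1); raising a suppressor (or lowering an
oncogenic protein) should lower it (OR < 1). Equivalently, plausibility
holds iff sign(ln OR) = s * sign(beta) with s = -1 for a suppressor and
+1 for an oncogenic protein. Everything else is discordant.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import pandas as pd

from .datatypes import AssocResult, ConcordanceVerdict, PqtlRecord
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


def concordance_rule(role: str, beta_sign: str, or_direction: str) -> str:
    """Classify one (role, beta sign, OR direction) triple.

    role: 'suppressor' | 'oncogenic'; beta_sign: '+' | '-';
    or_direction: 'risk' (OR > 1) | 'protective' (OR < 1).
    """
    if role not in ("suppressor", "oncogenic"):
        raise ValidationError(f"unknown role {role!r}")
    if beta_sign not in ("+", "-"):
        raise ValidationError(f"beta_sign must be '+' or '-', got {beta_sign!r}")
    if or_direction not in ("risk", "protective"):
        raise ValidationError(f"unknown or_direction {or_direction!r}")
    s = -1 if role == "suppressor" else 1
    b = 1 if beta_sign == "+" else -1
    o = 1 if or_direction == "risk" else -1
    if s * b == o:
        return "plausible_risk" if o == 1 else "plausible_protective"
    return "discordant"


def _beta_sign(beta: float) -> str:
    if beta == 0.0:
        raise ValidationError("beta is exactly 0: effect direction undefined")
    return "+" if beta > 0 else "-"


def _or_direction(or_estimate: float) -> str:
    if or_estimate == 1.0:
        raise ValidationError("OR is exactly 1: direction undefined")
    return "risk" if or_estimate > 1.0 else "protective"


def select_candidates(
    assoc: Sequence[AssocResult],
    pqtl: Sequence[PqtlRecord],
    roles: Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[list[ConcordanceVerdict], pd.DataFrame]:
    """Evaluate concordance for every significant SNP (additive p < alpha).

    OR direction is taken from the additive model. Returns the plausible
    verdicts plus a full table including discordant and unevaluable rows
    (missing role/record, zero beta, OR exactly 1 - reported, never
    silently dropped).
    """
    additive = {r.snp_id: r for r in assoc if r.model == "additive"}
    records: dict[str, list[PqtlRecord]] = {}
    for rec in pqtl:
        records.setdefault(rec.snp_id, []).append(rec)

    rows = []
    plausible: list[ConcordanceVerdict] = []
    for snp_id, res in additive.items():
        if res.p_value >= alpha:
            continue
        recs = records.get(snp_id)
        if not recs:
            rows.append(dict(snp_id=snp_id, protein_id=None, role=None, beta_sign=None,
                             or_direction=None, or_estimate=res.or_estimate,
                             p_value=res.p_value, verdict="unevaluable:no_pqtl_record"))
            logger.warning("%s: significant but no pQTL record", snp_id)
            continue
        for rec in recs:
            role = roles.get(rec.target_protein_id)
            base = dict(snp_id=snp_id, protein_id=rec.target_protein_id,
                        or_estimate=res.or_estimate, p_value=res.p_value)
            if role not in ("suppressor", "oncogenic"):
                rows.append({**base, "role": role, "beta_sign": None, "or_direction": None,
                             "verdict": "unevaluable:no_role"})
                logger.warning("%s/%s: no role label", snp_id, rec.target_protein_id)
                continue
            try:
                bsign = _beta_sign(rec.beta)
                odir = _or_direction(res.or_estimate)
            except ValidationError as exc:
                rows.append({**base, "role": role, "beta_sign": None, "or_direction": None,
                             "verdict": f"unevaluable:{exc}"})
                continue
            verdict = concordance_rule(role, bsign, odir)
            rows.append({**base, "role": role, "beta_sign": bsign,
                         "or_direction": odir, "verdict": verdict})
            if verdict.startswith("plausible"):
                plausible.append(
                    ConcordanceVerdict(snp_id, rec.target_protein_id, role, bsign, odir, verdict)
                )
    table = pd.DataFrame(
        rows,
        columns=["snp_id", "protein_id", "role", "beta_sign", "or_direction",
                 "or_estimate", "p_value", "verdict"],
    )
    return plausible, table


def verdict_report(verdicts: pd.DataFrame) -> dict:
    """Render the 8-row sign truth table with per-SNP assignments.

    Returns a JSON-serializable dict; pair with ``pd.DataFrame`` for TSV.
    """
    truth_rows = []
    for role in ("suppressor", "oncogenic"):
        for beta_sign in ("+", "-"):
            for or_direction in ("risk", "protective"):
                verdict = concordance_rule(role, beta_sign, or_direction)
                if len(verdicts):
                    mask = (
                        (verdicts["role"] == role)
                        & (verdicts["beta_sign"] == beta_sign)
                        & (verdicts["or_direction"] == or_direction)
                    )
                    snps = sorted(verdicts.loc[mask, "snp_id"].tolist())
                else:
                    snps = []
                truth_rows.append(
                    dict(role=role, beta_sign=beta_sign, or_direction=or_direction,
                         verdict=verdict, snp_ids=snps)
                )
    evaluable = verdicts[~verdicts["verdict"].astype(str).str.startswith("unevaluable")] \
        if len(verdicts) else verdicts
    n_plausible = int(evaluable["verdict"].astype(str).str.startswith("plausible").sum()) \
        if len(verdicts) else 0
    n_discordant = int((evaluable["verdict"] == "discordant").sum()) if len(verdicts) else 0
    return {
        "truth_table": truth_rows,
        "n_plausible": n_plausible,
        "n_discordant": n_discordant,
        "n_unevaluable": int(len(verdicts) - len(evaluable)) if len(verdicts) else 0,
    }
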