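"""Core in-memory containers shared across pipeline stages.

Conventions: genotype dosages count effect alleles (0/1/2, -1 = missing);
genomic coordinates are 1-based inclusive (VCF convention); protein
matrices are proteins x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

MISSING = -1  # sentinel dosage for an uncalled genotype


@dataclass
class ProteinMatrix:
    """Protein abundance matrix with per-sample metadata.

    ``values`` may hold raw or log2 abundances depending on provenance;
    ``is_log2`` records which. ``group`` is 'case'/'control' for plasma
    and 'tumor'/'adjacent' for tissue; paired designs carry a ``pair_id``
    per column.
    """

    values: np.ndarray  # proteins x samples, float
    protein_ids: list[str]
    sample_ids: list[str]
    group: list[str]
    compartment: str  # 'plasma' or 'tissue'
    pair_id: Optional[list[str]] = None
    is_log2: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein_ids")
        if len(self.group) != len(self.sample_ids):
            raise ValidationError("group labels must align with sample_ids")
        if self.pair_id is not None and len(self.pair_id) != len(self.sample_ids):
            raise ValidationError("pair_id labels must align with sample_ids")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy_with(self, **kwargs) -> "ProteinMatrix":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)


@dataclass
class GenotypeData:
    """Biallelic genotypes as effect-allele dosages with SNP and sample metadata."""

    dosages: np.ndarray  # snps x samples, int8; MISSING == -1
    snp_ids: list[str]
    chromosome: list[str]
    position: np.ndarray  # 1-based bp
    effect_allele: list[str]
    other_allele: list[str]
    sample_ids: list[str]
    status: Optional[np.ndarray] = None  # 1 = case, 0 = control
    age_group: Optional[np.ndarray] = None  # 1 = >60, 0 = <=60

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.position = np.asarray(self.position, dtype=np.int64)
        n_snp, n_smp = self.dosages.shape
        if len(self.snp_ids) != n_snp or len(self.sample_ids) != n_smp:
            raise ValidationError("dosage matrix does not match snp/sample id lengths")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate snp_id in genotype data")
        valid = np.isin(self.dosages, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValidationError("dosages must be 0/1/2 or -1 (missing)")
        for arr_name in ("status", "age_group"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int8)
                if arr.shape != (n_smp,):
                    raise ValidationError(f"{arr_name} must have one entry per sample")
                setattr(self, arr_name, arr)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def dosage_row(self, snp_id: str) -> np.ndarray:
        return self.dosages[self.snp_index(snp_id)]


@dataclass(frozen=True)
class PqtlRecord:
    """One SNP -> protein effect from a pQTL catalog (beta on the effect allele)."""

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    target_protein_id: str
    gene: str
    beta: float
    p_value: float
    source: str

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: alleles must be distinct")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"{self.snp_id}: p_value must lie in (0, 1]")


@dataclass(frozen=True)
class SnpPanelStats:
    """Reference-panel allele-frequency summary for one SNP."""

    snp_id: str
    maf: float
    effect_allele_freq: float
    n_nonmissing: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: maf outside [0, 0.5]")


@dataclass(frozen=True)
class ContingencyTable:
    """Genotype x case/control counts for one SNP (Table-2 layout)."""

    snp_id: str
    cases: tuple[int, int, int]  # (ref-hom, het, alt-hom)
    controls: tuple[int, int, int]
    n_missing: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cases + self.controls):
            raise ValidationError(f"{self.snp_id}: negative genotype count")

    @property
    def n_cases(self) -> int:
        return sum(self.cases)

    @property
    def n_controls(self) -> int:
        return sum(self.controls)


@dataclass
class AssocResult:
    """Odds ratio, Wald CI and p-value for one SNP under one genetic model."""

    snp_id: str
    model: str  # het_vs_ref | hom_vs_ref | dominant | recessive | additive
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    n_case_exposed: Optional[int] = None
    n_control_exposed: Optional[int] = None
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValidationError(
                f"{self.snp_id}/{self.model}: CI does not bracket the estimate"
            )
        if self.or_estimate <= 0:
            raise ValidationError(f"{self.snp_id}/{self.model}: OR must be positive")


@dataclass(frozen=True)
class ConcordanceVerdict:
    """Regulation-pattern classification of one SNP/protein pair."""

    snp_id: str
    protein_id: str
    role: str  # suppressor | oncogenic
    beta_sign: str  # '+' | '-'
    or_direction: str  # 'risk' (OR>1) | 'protective' (OR<1)
    verdict: str  # plausible_risk | plausible_protective | discordant


@dataclass
class RocResult:
    """AUC with bootstrap CI for a single or combined marker."""

    marker: str
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    orientation: str = "higher_in_cases"

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValidationError("AUC outside [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValidationError("AUC CI does not bracket the estimate")


def assoc_results_frame(results: Sequence[AssocResult]) -> pd.DataFrame:
    """Tabulate association results (one row per SNP x model)."""
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "model": [r.model for r in results],
            "n_case_exposed": [r.n_case_exposed for r in results],
            "n_control_exposed": [r.n_control_exposed for r in results],
            "or": [r.or_estimate for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted": [r.adjusted for r in results],
        }
    )
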