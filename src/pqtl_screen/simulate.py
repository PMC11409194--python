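"""Synthetic case-control cohort generator.

Generates every data product the screening pipeline consumes: biallelic
genotypes in Hardy-Weinberg equilibrium with block-wise LD at a target
r-squared, disease status from an additive logistic liability model with a
binary age covariate, and plasma/tissue proteomics with planted
case-control shifts and per-allele pQTL effects.

LD within a block is induced by a Gaussian-copula haplotype scheme: each
haplotype's allele indicators come from thresholding latent standard
normals whose correlation with the block anchor is calibrated (bivariate-
normal orthant probability, solved by root finding) so that the realized
dosage correlation squared matches ``target_r2``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .datatypes import GenotypeData, PqtlRecord, ProteinMatrix
from .exceptions import SimulationError, ValidationError

# ------------------------------------------------------------------ specs


@dataclass(frozen=True)
class LocusSpec:
    """One simulated biallelic locus.

    ``maf`` is the effect-allele frequency (kept in (0, 0.5] so the effect
    allele is the minor allele). ``target_r2`` is the desired dosage
    r-squared with the anchor (first-listed) locus of ``ld_block``; the
    anchor itself must use 0. ``per_allele_log_or`` enters the disease
    model; ``pqtl_beta`` is the per-allele shift in log2 abundance of
    ``target_protein``.
    """

    snp_id: str
    chromosome: str
    position: int
    effect_allele: str
    maf: float
    ld_block: str
    target_r2: float = 0.0
    per_allele_log_or: float = 0.0
    pqtl_beta: float = 0.0
    target_protein: Optional[str] = None
    other_allele: str = "A"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: maf must lie in (0, 0.5]")
        if not (0.0 <= self.target_r2 < 1.0):
            raise ValidationError(f"{self.snp_id}: target_r2 must lie in [0, 1)")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class ProteinSpec:
    """One simulated protein and its planted differential-expression role.

    Suppressor proteins are planted lower in cases/tumors (negative
    shifts), oncogenic proteins higher, null proteins unshifted.
    """

    protein_id: str
    gene: str
    chromosome: str
    tss_position: int
    role: str = "null"  # suppressor | oncogenic | null
    plasma_shift: float = 0.0  # log2 FC case - control
    tissue_shift: float = 0.0  # log2 FC tumor - adjacent

    def __post_init__(self) -> None:
        if self.role not in ("suppressor", "oncogenic", "null"):
            raise ValidationError(f"{self.protein_id}: unknown role {self.role!r}")
        if self.role == "suppressor" and not (
            self.plasma_shift < 0 and self.tissue_shift < 0
        ):
            raise ValidationError(f"{self.protein_id}: suppressor shifts must be < 0")
        if self.role == "oncogenic" and not (
            self.plasma_shift > 0 and self.tissue_shift > 0
        ):
            raise ValidationError(f"{self.protein_id}: oncogenic shifts must be > 0")
        if self.role == "null" and (self.plasma_shift or self.tissue_shift):
            raise ValidationError(f"{self.protein_id}: null role requires zero shifts")


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort."""

    n_cases: int = 500
    n_controls: int = 500
    n_tissue_pairs: int = 65
    loci: list[LocusSpec] = field(default_factory=list)
    proteins: list[ProteinSpec] = field(default_factory=list)
    disease_intercept: float = 0.0
    age_effect: float = 0.0  # log-odds per age-group increment (>60 vs <=60)
    prob_age_over60: float = 0.5
    noise_sd: float = 1.0
    subject_sd: float = 0.5  # shared tumor/adjacent subject effect (tissue pairs)
    baseline_log2: float = 20.0
    n_panel: int = 200  # reference-panel individuals for MAF/LD
    max_draw_factor: int = 100  # rejection-sampling bound, x (n_cases+n_controls)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        ids = [l.snp_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate snp_id in loci")
        pids = [p.protein_id for p in self.proteins]
        if len(set(pids)) != len(pids):
            raise ValidationError("duplicate protein_id in proteins")
        known = set(pids)
        for locus in self.loci:
            if locus.target_protein is not None and locus.target_protein not in known:
                raise ValidationError(
                    f"{locus.snp_id}: unknown target_protein {locus.target_protein!r}"
                )


# ------------------------------------------------- copula LD calibration


@functools.lru_cache(maxsize=1024)
def _latent_rho(p_a: float, p_b: float, target_r2: float) -> float:
    """Latent-normal correlation giving haplotype-allele correlation sqrt(target_r2).

    Allele indicators arise from thresholding standard normals at the
    allele-frequency quantiles; their correlation follows from the
    bivariate-normal orthant probability, monotone in the latent rho.
    """
    if target_r2 == 0.0:
        return 0.0
    r_target = float(np.sqrt(target_r2))
    z_a, z_b = stats.norm.ppf(p_a), stats.norm.ppf(p_b)
    denom = np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))

    def allele_corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [z_a, z_b], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - p_a * p_b) / denom

    upper = 0.999999
    if allele_corr(upper) < r_target:
        raise ValidationError(
            f"target_r2={target_r2} unattainable for allele frequencies "
            f"{p_a:.3f}/{p_b:.3f}"
        )
    return float(optimize.brentq(lambda r: allele_corr(r) - r_target, 0.0, upper))


def _draw_dosages(
    loci: list[LocusSpec], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an (n_loci x n) dosage matrix honouring the LD-block structure."""
    dosages = np.empty((len(loci), n), dtype=np.int8)
    index = {l.snp_id: i for i, l in enumerate(loci)}
    blocks: dict[str, list[LocusSpec]] = {}
    for locus in loci:
        blocks.setdefault(locus.ld_block, []).append(locus)
    for members in blocks.values():
        anchor = members[0]
        # two haplotypes per individual, latent normals shared within block
        z_anchor = rng.standard_normal((2, n))
        for locus in members:
            if locus is anchor:
                z = z_anchor
            else:
                rho = _latent_rho(anchor.maf, locus.maf, locus.target_r2)
                z = rho * z_anchor + np.sqrt(1.0 - rho**2) * rng.standard_normal((2, n))
            alleles = z < stats.norm.ppf(locus.maf)
            dosages[index[locus.snp_id]] = alleles.sum(axis=0).astype(np.int8)
    return dosages


def _genotype_data(
    loci: list[LocusSpec], dosages: np.ndarray, sample_ids: list[str]
) -> GenotypeData:
    return GenotypeData(
        dosages=dosages,
        snp_ids=[l.snp_id for l in loci],
        chromosome=[l.chromosome for l in loci],
        position=np.array([l.position for l in loci]),
        effect_allele=[l.effect_allele for l in loci],
        other_allele=[l.other_allele for l in loci],
        sample_ids=sample_ids,
    )


# ------------------------------------------------------------ operations


def simulate_genotypes(
    config: SimulationConfig, n: Optional[int] = None, prefix: str = "S"
) -> GenotypeData:
    """Simulate an unlabelled genotype cohort of ``n`` individuals.

    Defaults to ``n_cases + n_controls`` individuals. Loci are in HWE at
    their MAF; within-block dosage r-squared approximates ``target_r2``;
    distinct blocks are independent. Deterministic under ``config.seed``.
    """
    if n is None:
        n = config.n_cases + config.n_controls
    rng = np.random.default_rng([config.seed, 0])
    dosages = _draw_dosages(config.loci, n, rng)
    ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
    return _genotype_data(config.loci, dosages, ids)


def simulate_panel(config: SimulationConfig) -> GenotypeData:
    """Simulate the reference genotype panel used for MAF and LD filters."""
    rng = np.random.default_rng([config.seed, 3])
    dosages = _draw_dosages(config.loci, config.n_panel, rng)
    ids = [f"P{i + 1:05d}" for i in range(config.n_panel)]
    return _genotype_data(config.loci, dosages, ids)


def simulate_phenotype(
    genotypes: GenotypeData, config: SimulationConfig
) -> GenotypeData:
    """Assign age and case/control status; resample to the requested arm sizes.

    Disease status follows P(case | g, a) = logistic(intercept +
    sum(log_or * g) + age_effect * a) with a ~ Bernoulli(prob_age_over60).
    Individuals are drawn from the population model until ``n_cases`` cases
    and ``n_controls`` controls accrue (case-control sampling, under which
    odds ratios are preserved); additional genotype draws beyond the input
    cohort use the same generator. Raises :class:`SimulationError` once
    ``max_draw_factor`` x (n_cases + n_controls) draws are exhausted.
    """
    rng = np.random.default_rng([config.seed, 1])
    log_ors = np.array([l.per_allele_log_or for l in config.loci])
    n_target = config.n_cases + config.n_controls
    max_draws = config.max_draw_factor * n_target

    kept_dosage: list[np.ndarray] = []
    kept_age: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    n_case = n_ctrl = 0
    total_drawn = 0
    pending = np.asarray(genotypes.dosages, dtype=np.int8)

    while True:
        chunk = pending
        pending = None
        n_chunk = chunk.shape[1]
        total_drawn += n_chunk
        age = (rng.random(n_chunk) < config.prob_age_over60).astype(np.int8)
        eta = (
            config.disease_intercept
            + log_ors @ chunk.astype(float)
            + config.age_effect * age
        )
        status = (rng.random(n_chunk) < expit(eta)).astype(np.int8)

        take_case = min(config.n_cases - n_case, int(status.sum()))
        take_ctrl = min(config.n_controls - n_ctrl, int((1 - status).sum()))
        case_idx = np.flatnonzero(status == 1)[:take_case]
        ctrl_idx = np.flatnonzero(status == 0)[:take_ctrl]
        keep = np.concatenate([case_idx, ctrl_idx])
        if keep.size:
            kept_dosage.append(chunk[:, keep])
            kept_age.append(age[keep])
            kept_status.append(status[keep])
            n_case += take_case
            n_ctrl += take_ctrl
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
        if total_drawn >= max_draws:
            raise SimulationError(
                f"could not accrue {config.n_cases} cases / {config.n_controls} "
                f"controls within {max_draws} draws "
                f"(got {n_case}/{n_ctrl}); adjust disease_intercept"
            )
        pending = _draw_dosages(config.loci, n_target, rng)

    dosages = np.concatenate(kept_dosage, axis=1)
    status = np.concatenate(kept_status)
    age = np.concatenate(kept_age)
    order = np.argsort(-status, kind="stable")  # cases first, stable draw order
    dosages, status, age = dosages[:, order], status[order], age[order]
    ids = [f"C{i + 1:05d}" if s else f"K{i + 1:05d}" for i, s in enumerate(status)]
    out = _genotype_data(config.loci, dosages, ids)
    out.status = status
    out.age_group = age
    return out


def _protein_effects(
    config: SimulationConfig, dosages: np.ndarray, snp_index: dict[str, int]
) -> np.ndarray:
    """Per-protein x per-sample pQTL contribution (beta * dosage sums)."""
    effects = np.zeros((len(config.proteins), dosages.shape[1]))
    pidx = {p.protein_id: i for i, p in enumerate(config.proteins)}
    for locus in config.loci:
        if locus.target_protein is not None and locus.pqtl_beta != 0.0:
            effects[pidx[locus.target_protein]] += (
                locus.pqtl_beta * dosages[snp_index[locus.snp_id]].astype(float)
            )
    return effects


def simulate_proteomics(
    genotypes: GenotypeData, config: SimulationConfig
) -> tuple[ProteinMatrix, ProteinMatrix]:
    """Simulate plasma (cohort samples) and paired tissue (fresh subjects) matrices.

    log2 abundance = baseline + role shift * 1[case or tumor] +
    pqtl_beta * dosage + N(0, noise_sd). Tissue pairs share a subject
    effect and their own fresh genotypes (tissue donors are a separate
    series from the GWAS cohort).
    """
    if genotypes.status is None:
        raise ValidationError("simulate_proteomics requires phenotype status")
    rng = np.random.default_rng([config.seed, 2])
    n_prot = len(config.proteins)
    baselines = config.baseline_log2 + rng.normal(0.0, 2.0, size=n_prot)
    plasma_shift = np.array([p.plasma_shift for p in config.proteins])
    tissue_shift = np.array([p.tissue_shift for p in config.proteins])
    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}

    # plasma: over the case-control cohort
    n_smp = genotypes.n_samples
    is_case = genotypes.status.astype(float)
    values = (
        baselines[:, None]
        + plasma_shift[:, None] * is_case[None, :]
        + _protein_effects(config, genotypes.dosages, snp_index)
        + rng.normal(0.0, config.noise_sd, size=(n_prot, n_smp))
    )
    plasma = ProteinMatrix(
        values=values,
        protein_ids=[p.protein_id for p in config.proteins],
        sample_ids=list(genotypes.sample_ids),
        group=["case" if s else "control" for s in genotypes.status],
        compartment="plasma",
    )

    # tissue: fresh paired subjects, tumor + adjacent columns
    n_pairs = config.n_tissue_pairs
    pair_dosages = _draw_dosages(config.loci, n_pairs, rng)
    pair_effects = _protein_effects(config, pair_dosages, snp_index)
    subject = rng.normal(0.0, config.subject_sd, size=(1, n_pairs))
    tumor = (
        baselines[:, None]
        + tissue_shift[:, None]
        + pair_effects
        + subject
        + rng.normal(0.0, config.noise_sd, size=(n_prot, n_pairs))
    )
    adjacent = (
        baselines[:, None]
        + pair_effects
        + subject
        + rng.normal(0.0, config.noise_sd, size=(n_prot, n_pairs))
    )
    pair_ids = [f"T{i + 1:04d}" for i in range(n_pairs)]
    values = np.empty((n_prot, 2 * n_pairs))
    values[:, 0::2] = tumor
    values[:, 1::2] = adjacent
    sample_ids, groups, pair_col = [], [], []
    for pid in pair_ids:
        sample_ids += [f"{pid}_tumor", f"{pid}_adjacent"]
        groups += ["tumor", "adjacent"]
        pair_col += [pid, pid]
    tissue = ProteinMatrix(
        values=values,
        protein_ids=[p.protein_id for p in config.proteins],
        sample_ids=sample_ids,
        group=groups,
        compartment="tissue",
        pair_id=pair_col,
    )
    return plasma, tissue


def catalog_records(config: SimulationConfig, source: str = "sim") -> list[PqtlRecord]:
    """pQTL catalog implied by the planted loci (one record per pQTL locus)."""
    records = []
    for locus in config.loci:
        if locus.target_protein is None:
            continue
        protein = next(p for p in config.proteins if p.protein_id == locus.target_protein)
        records.append(
            PqtlRecord(
                snp_id=locus.snp_id,
                chromosome=locus.chromosome,
                position=locus.position,
                effect_allele=locus.effect_allele,
                other_allele=locus.other_allele,
                target_protein_id=locus.target_protein,
                gene=protein.gene,
                beta=locus.pqtl_beta,
                p_value=1e-8,
                source=source,
            )
        )
    return records


def annotation_frame(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table (gene, chrom, tss) for the simulated proteins."""
    return pd.DataFrame(
        {
            "gene": [p.gene for p in config.proteins],
            "chrom": [p.chromosome for p in config.proteins],
            "tss": [p.tss_position for p in config.proteins],
        }
    )


def simulate_cohort(config: SimulationConfig) -> dict:
    """Run the full generator; returns all data products keyed by name."""
    genotypes = simulate_phenotype(simulate_genotypes(config), config)
    plasma, tissue = simulate_proteomics(genotypes, config)
    return {
        "genotypes": genotypes,
        "panel": simulate_panel(config),
        "plasma": plasma,
        "tissue": tissue,
        "catalog": catalog_records(config),
        "annotation": annotation_frame(config),
        "config": config,
    }


def write_cohort(outputs: dict, directory) -> dict[str, Path]:
    """Write all simulated products to ``directory`` (VCF + TSVs).

    Round-trips losslessly through :mod:`pqtl_screen.io`; byte-identical
    across runs with the same seed.
    """
    from . import io as _io  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.vcf",
        "panel": directory / "panel.vcf",
        "plasma": directory / "plasma.tsv",
        "tissue": directory / "tissue.tsv",
        "covariates": directory / "covariates.tsv",
        "catalog": directory / "catalog.tsv",
        "annotation": directory / "annotation.tsv",
    }
    _io.write_vcf(outputs["genotypes"], paths["genotypes"])
    _io.write_vcf(outputs["panel"], paths["panel"])
    _io.write_protein_matrix(outputs["plasma"], paths["plasma"])
    _io.write_protein_matrix(outputs["tissue"], paths["tissue"])
    _io.write_covariates(outputs["genotypes"], paths["covariates"])
    _io.write_catalog(outputs["catalog"], paths["catalog"])
    outputs["annotation"].to_csv(paths["annotation"], sep="\t", index=False)
    return paths


# ------------------------------------------------------- default cohort


def default_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale default cohort: 500/500 cases/controls, 50 loci, 200 proteins.

    Twenty differential proteins (12 suppressor, 8 oncogenic) among 180
    nulls; 20 pQTL loci targeting them with a mix of concordant and
    discordant planted disease effects, 10 LD partner loci (r2 = 0.9) to
    exercise pruning, and 20 unlinked null filler loci.
    """
    proteins: list[ProteinSpec] = []
    for i in range(200):
        chrom = str(i % 22 + 1)
        tss = 1_000_000 + 2_000_000 * (i // 22)
        if i < 12:
            role, ps, ts = "suppressor", -1.0, -1.0
        elif i < 20:
            role, ps, ts = "oncogenic", 1.0, 1.0
        else:
            role, ps, ts = "null", 0.0, 0.0
        proteins.append(
            ProteinSpec(
                protein_id=f"P{i + 1:03d}",
                gene=f"G{i + 1:03d}",
                chromosome=chrom,
                tss_position=tss,
                role=role,
                plasma_shift=ps,
                tissue_shift=ts,
            )
        )

    loci: list[LocusSpec] = []
    log15 = float(np.log(1.5))
    for i in range(20):
        target = proteins[i]
        # suppressor targets i<12: concordant risk (beta<0, OR>1) for i<6,
        # concordant protective (beta>0, OR<1) for 6<=i<9, discordant for
        # 9<=i<12; oncogenic targets: concordant risk for i<16, null OR after.
        if target.role == "suppressor":
            beta = -0.5 if (i < 6 or i >= 9) else 0.5
            log_or = log15 if i < 6 else -log15
        else:
            beta = 0.5
            log_or = log15 if i < 16 else 0.0
        loci.append(
            LocusSpec(
                snp_id=f"snp{i + 1:03d}",
                chromosome=target.chromosome,
                position=target.tss_position + 50_000,
                effect_allele="G",
                other_allele="A",
                maf=0.3,
                ld_block=f"B{i + 1:02d}",
                per_allele_log_or=log_or,
                pqtl_beta=beta,
                target_protein=target.protein_id,
            )
        )
    for i in range(10):  # LD partners of the first 10 pQTL loci
        anchor = loci[i]
        loci.append(
            LocusSpec(
                snp_id=f"snp{i + 21:03d}",
                chromosome=anchor.chromosome,
                position=anchor.position + 10_000,
                effect_allele="G",
                other_allele="A",
                maf=0.3,
                ld_block=anchor.ld_block,
                target_r2=0.9,
                pqtl_beta=anchor.pqtl_beta * 0.9,
                target_protein=anchor.target_protein,
            )
        )
    for i in range(20):  # unlinked null filler loci
        loci.append(
            LocusSpec(
                snp_id=f"snp{i + 31:03d}",
                chromosome=str(i % 22 + 1),
                position=60_000_000 + 1_000_000 * i,
                effect_allele="C",
                other_allele="T",
                maf=0.25,
                ld_block=f"N{i + 1:02d}",
            )
        )
    return SimulationConfig(loci=loci, proteins=proteins, seed=seed)
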