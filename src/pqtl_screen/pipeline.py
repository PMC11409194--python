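"""Orchestration of the full screening pipeline.

Stages run in the study's order: differential expression and
intersection -> catalog merge and cis/MAF/LD variant filtering ->
case-control association -> concordance classification -> biomarker ROC
on the final candidates' target proteins. Each stage's input/output
counts land in a machine-readable manifest; a stage failure halts the
run with the manifest recording the stages completed. Deterministic
under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import association, biomarker, concordance, diffexpr, io, pqtl_select
from .datatypes import GenotypeData, assoc_results_frame
from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    plasma: str
    tissue: str
    covariates: str
    catalogs: list[str]
    annotation: str
    panel: str
    genotypes: str
    out_dir: str
    alpha: float = 0.05
    maf_threshold: float = pqtl_select.DEFAULT_MAF_THRESHOLD
    r2_threshold: float = pqtl_select.DEFAULT_R2_THRESHOLD
    cis_window: int = pqtl_select.DEFAULT_CIS_WINDOW
    models: tuple[str, ...] = association.MODELS
    adjust: tuple[str, ...] = ("age_group",)
    normalize_method: str = "median_center"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0 <= self.maf_threshold < 0.5):
            raise ValidationError("maf_threshold must lie in [0, 0.5)")
        if not (0 < self.r2_threshold <= 1):
            raise ValidationError("r2_threshold must lie in (0, 1]")
        if self.cis_window < 0:
            raise ValidationError("cis_window must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        if "adjust" in raw:
            raw["adjust"] = tuple(raw["adjust"])
        return cls(**raw)

    @classmethod
    def for_cohort_dir(cls, directory, out_dir, **overrides) -> "PipelineConfig":
        """Config pointing at a directory written by ``write_cohort``."""
        d = Path(directory)
        return cls(
            plasma=str(d / "plasma.tsv"),
            tissue=str(d / "tissue.tsv"),
            covariates=str(d / "covariates.tsv"),
            catalogs=[str(d / "catalog.tsv")],
            annotation=str(d / "annotation.tsv"),
            panel=str(d / "panel.vcf"),
            genotypes=str(d / "genotypes.vcf"),
            out_dir=str(out_dir),
            **overrides,
        )


def _subset_snps(genotypes: GenotypeData, snp_ids: Sequence[str]) -> GenotypeData:
    idx = [genotypes.snp_index(s) for s in snp_ids]
    return GenotypeData(
        dosages=genotypes.dosages[idx],
        snp_ids=[genotypes.snp_ids[i] for i in idx],
        chromosome=[genotypes.chromosome[i] for i in idx],
        position=genotypes.position[idx],
        effect_allele=[genotypes.effect_allele[i] for i in idx],
        other_allele=[genotypes.other_allele[i] for i in idx],
        sample_ids=list(genotypes.sample_ids),
        status=genotypes.status,
        age_group=genotypes.age_group,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as summary.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"schema_version": 1, "seed": config.seed, "stages": {}}

    def _finish(stage: str, error: Optional[Exception] = None) -> None:
        if error is not None:
            manifest["stages"][stage] = {"status": "failed", "error": str(error)}
        with open(out / "summary.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    stage = "diffexpr"
    try:
        covariates = io.read_covariates(config.covariates)
        plasma = io.read_protein_matrix(config.plasma, "plasma", covariates)
        tissue = io.read_protein_matrix(config.tissue, "tissue")
        plasma = diffexpr.normalize(plasma, config.normalize_method)
        tissue = diffexpr.normalize(tissue, config.normalize_method)
        de_plasma = diffexpr.de_test_unpaired(plasma, config.alpha)
        de_tissue = diffexpr.de_test_paired(tissue, config.alpha)
        roles = diffexpr.intersect_consistent(de_plasma, de_tissue, config.alpha)
        diffexpr.de_results_frame(de_plasma, "plasma").to_csv(
            out / "de_plasma.tsv", sep="\t", index=False)
        diffexpr.de_results_frame(de_tissue, "tissue").to_csv(
            out / "de_tissue.tsv", sep="\t", index=False)
        roles.to_csv(out / "roles.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_proteins": plasma.n_proteins,
            "n_plasma_significant": sum(r.direction != "flat" for r in de_plasma),
            "n_tissue_significant": sum(r.direction != "flat" for r in de_tissue),
            "n_intersect": int(len(roles)),
            "n_up": int((roles["role"] == "oncogenic").sum()),
            "n_down": int((roles["role"] == "suppressor").sum()),
        }
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        _finish(stage, exc)
        raise

    stage = "pqtl_select"
    try:
        catalogs = [io.read_catalog(p) for p in config.catalogs]
        panel = io.read_genotypes(config.panel)
        annotation = io.read_annotation(config.annotation)
        merged = pqtl_select.merge_catalogs(catalogs, set(roles["protein_id"]))
        cis = pqtl_select.filter_cis(merged, annotation, config.cis_window)
        stats = pqtl_select.compute_maf(panel)
        common = pqtl_select.filter_maf(cis, stats, config.maf_threshold)
        pruned = pqtl_select.ld_prune(common, panel, config.r2_threshold)
        io.write_catalog(pruned, out / "selected_pqtl.tsv")
        manifest["stages"][stage] = {
            "status": "ok",
            "n_catalog": sum(len(c) for c in catalogs),
            "n_merged": len(merged),
            "n_cis": len(cis),
            "n_maf": len(common),
            "n_pruned": len(pruned),
        }
    except Exception as exc:  # noqa: BLE001
        _finish(stage, exc)
        raise

    stage = "association"
    try:
        genotypes = io.read_genotypes(config.genotypes)
        genotypes = io.attach_phenotype(genotypes, covariates)
        selected_snps = sorted({r.snp_id for r in pruned} & set(genotypes.snp_ids))
        scan_geno = _subset_snps(genotypes, selected_snps)
        results, flags = association.association_scan(
            scan_geno, config.models, config.adjust, config.alpha
        )
        frame = assoc_results_frame(results)
        frame["significant"] = frame.apply(
            lambda r: bool(flags.get(r.snp_id, False)), axis=1
        )
        add_p = {r.snp_id: r.p_value for r in results if r.model == "additive"}
        bonf = dict(zip(add_p, association.bonferroni(list(add_p.values()))))
        frame["bonferroni_additive"] = frame["snp_id"].map(bonf)
        frame.to_csv(out / "association.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_snps_tested": scan_geno.n_snps,
            "n_significant": int(sum(flags.values())),
        }
    except Exception as exc:  # noqa: BLE001
        _finish(stage, exc)
        raise

    stage = "concordance"
    try:
        role_map = dict(zip(roles["protein_id"], roles["role"]))
        plausible, verdicts = concordance.select_candidates(
            results, pruned, role_map, config.alpha
        )
        verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
        report = concordance.verdict_report(verdicts)
        with open(out / "verdict_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"][stage] = {
            "status": "ok",
            "n_evaluated": int(len(verdicts)),
            "n_plausible": len(plausible),
            "candidates": sorted(v.snp_id for v in plausible),
        }
    except Exception as exc:  # noqa: BLE001
        _finish(stage, exc)
        raise

    stage = "biomarker_eval"
    try:
        markers = sorted({v.protein_id for v in plausible} & set(plasma.protein_ids))
        roc_results = []
        if markers and genotypes.status is not None:
            status = np.array(
                [1 if g == "case" else 0 for g in plasma.group], dtype=int
            )
            rows = [plasma.protein_ids.index(m) for m in markers]
            for m, i in zip(markers, rows):
                roc_results.append(
                    biomarker.auc_mann_whitney(
                        plasma.values[i], status, marker=m, seed=config.seed
                    )
                )
            if len(markers) >= 2:
                roc_results.append(
                    biomarker.combined_score(
                        plasma.values[rows], status, marker_names=markers,
                        seed=config.seed,
                    )
                )
        biomarker.roc_results_frame(roc_results).to_csv(
            out / "roc.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_markers": len(markers),
            "aucs": {r.marker: round(r.auc, 6) for r in roc_results},
        }
    except Exception as exc:  # noqa: BLE001
        _finish(stage, exc)
        raise

    _finish(stage=None)
    return manifest
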