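"""Candidate pQTL-SNP selection: catalog merge, cis, MAF and LD filters.

Catalogs restricted to the LUAD-related proteins are merged (smallest
p-value wins per SNP/protein, with effect-allele harmonization across
sources), then filtered to cis variants (within a window of the target
gene's TSS, default +/- 1 Mb, closed interval), to MAF > threshold in a
user-supplied reference panel, and finally greedily LD-pruned so that no
two retained SNPs on a chromosome exceed the r-squared threshold.

LD is the squared Pearson correlation of effect-allele dosages
(composite LD): phase-free and deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeData, PqtlRecord, SnpPanelStats
from .exceptions import UndefinedLDError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000  # bp around the TSS; both catalogs' convention
DEFAULT_MAF_THRESHOLD = 0.05
DEFAULT_R2_THRESHOLD = 0.80


def merge_catalogs(
    catalogs: Sequence[Sequence[PqtlRecord]], restrict_to: Iterable[str]
) -> list[PqtlRecord]:
    """Union catalogs, restricted to ``restrict_to`` proteins, deduplicating.

    For a (snp_id, target_protein_id) seen in several sources the record
    with the smaller p-value is kept and the source labels joined with
    '+'. Effect-allele labels are harmonized per snp_id against the first
    record seen: a swapped effect/other pair flips the beta sign; alleles
    that neither match nor swap drop the record with a log entry.
    """
    keep: set[str] = set(restrict_to)
    canonical: dict[str, tuple[str, str]] = {}
    merged: dict[tuple[str, str], PqtlRecord] = {}
    for catalog in catalogs:
        for rec in catalog:
            if rec.target_protein_id not in keep:
                continue
            alleles = (rec.effect_allele, rec.other_allele)
            if rec.snp_id not in canonical:
                canonical[rec.snp_id] = alleles
            elif alleles != canonical[rec.snp_id]:
                if alleles == canonical[rec.snp_id][::-1]:
                    logger.warning(
                        "%s: swapped alleles in source %s; flipping beta sign",
                        rec.snp_id, rec.source,
                    )
                    rec = dataclasses.replace(
                        rec,
                        effect_allele=canonical[rec.snp_id][0],
                        other_allele=canonical[rec.snp_id][1],
                        beta=-rec.beta,
                    )
                else:
                    logger.warning(
                        "%s: irreconcilable alleles %s vs %s in source %s; dropped",
                        rec.snp_id, alleles, canonical[rec.snp_id], rec.source,
                    )
                    continue
            key = (rec.snp_id, rec.target_protein_id)
            prev = merged.get(key)
            if prev is None:
                merged[key] = rec
            else:
                sources = "+".join(sorted(set(prev.source.split("+")) | {rec.source}))
                best = rec if rec.p_value < prev.p_value else prev
                merged[key] = dataclasses.replace(best, source=sources)
    return list(merged.values())


def filter_cis(
    records: Sequence[PqtlRecord],
    gene_annotation: pd.DataFrame,
    window: int = DEFAULT_CIS_WINDOW,
) -> list[PqtlRecord]:
    """Keep SNPs on the target gene's chromosome within ``window`` bp of its TSS.

    The window is a closed interval: |position - TSS| == window is kept.
    ``gene_annotation`` needs columns gene, chrom, tss.
    """
    ann = gene_annotation.set_index("gene")
    out = []
    for rec in records:
        if rec.gene not in ann.index:
            logger.warning("%s: gene %s missing from annotation; dropped", rec.snp_id, rec.gene)
            continue
        row = ann.loc[rec.gene]
        if str(row["chrom"]) == str(rec.chromosome) and abs(rec.position - int(row["tss"])) <= window:
            out.append(rec)
    return out


def compute_maf(panel: GenotypeData) -> list[SnpPanelStats]:
    """Per-SNP minor allele frequency from reference-panel dosages.

    maf = min(f, 1-f) with f the effect-allele frequency over non-missing
    calls. All-missing SNPs get maf = NaN and a log entry.
    """
    out = []
    for i, snp in enumerate(panel.snp_ids):
        row = panel.dosages[i]
        obs = row[row != MISSING]
        if obs.size == 0:
            logger.warning("%s: all genotypes missing; MAF undefined", snp)
            out.append(SnpPanelStats(snp, maf=0.0, effect_allele_freq=float("nan"), n_nonmissing=0))
            continue
        f = float(obs.sum()) / (2.0 * obs.size)
        out.append(SnpPanelStats(snp, maf=min(f, 1.0 - f), effect_allele_freq=f, n_nonmissing=int(obs.size)))
    return out


def filter_maf(
    records: Sequence[PqtlRecord],
    stats: Sequence[SnpPanelStats],
    threshold: float = DEFAULT_MAF_THRESHOLD,
) -> list[PqtlRecord]:
    """Keep records whose panel MAF is strictly greater than ``threshold``."""
    by_snp = {s.snp_id: s for s in stats}
    out = []
    for rec in records:
        st = by_snp.get(rec.snp_id)
        if st is None or st.n_nonmissing == 0:
            logger.warning("%s: no panel statistics; dropped", rec.snp_id)
            continue
        if st.maf > threshold:
            out.append(rec)
    return out


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of effect-allele dosages (composite LD)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("dosage vectors must be equal-length 1-D with >= 3 entries")
    if a.std() == 0.0 or b.std() == 0.0:
        raise UndefinedLDError("monomorphic locus: LD undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def ld_prune(
    records: Sequence[PqtlRecord],
    panel: GenotypeData,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[PqtlRecord]:
    """Greedy LD pruning: best (smallest pQTL p) SNP first.

    Records are sorted by p-value ascending (ties: chromosome, position,
    snp_id); a record is accepted iff its r-squared with every
    already-accepted SNP on the same chromosome is < ``r2_threshold``.
    SNPs absent from the panel are treated as unlinked with a log entry.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValidationError("r2_threshold must lie in (0, 1]")
    snp_rows = {s: i for i, s in enumerate(panel.snp_ids)}
    ordered = sorted(records, key=lambda r: (r.p_value, r.chromosome, r.position, r.snp_id))
    accepted: list[PqtlRecord] = []
    accepted_snps: set[str] = set()
    for rec in ordered:
        if rec.snp_id in accepted_snps:
            accepted.append(rec)  # same SNP already retained for another protein
            continue
        row = snp_rows.get(rec.snp_id)
        if row is None:
            logger.warning("%s: absent from panel; treated as unlinked", rec.snp_id)
            ok = True
        else:
            ok = True
            for prev in accepted:
                if prev.chromosome != rec.chromosome:
                    continue
                prev_row = snp_rows.get(prev.snp_id)
                if prev_row is None:
                    continue
                if ld_r2(panel.dosages[row], panel.dosages[prev_row]) >= r2_threshold:
                    ok = False
                    break
        if ok:
            accepted.append(rec)
            accepted_snps.add(rec.snp_id)
    return accepted
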