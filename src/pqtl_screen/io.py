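"""File formats: VCF 4.2 genotypes (GT only), TSV matrices and catalogs.

All coordinates are 1-based inclusive (VCF convention). In VCF output the
REF column carries the non-effect allele and ALT the effect allele, so
ALT-allele counts equal effect-allele dosages.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, GenotypeData, PqtlRecord, ProteinMatrix
from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "protein_id", "gene", "beta", "p_value", "source",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(genotypes: GenotypeData, path) -> None:
    """Write genotypes as minimal VCF 4.2 with only the GT FORMAT field."""
    path = Path(path)
    order = np.lexsort(
        (genotypes.position, np.array([_chrom_key(c) for c in genotypes.chromosome]))
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pqtl-screen\n")
        seen = []
        for c in (genotypes.chromosome[i] for i in order):
            if c not in seen:
                seen.append(c)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        for i in order:
            gts = "\t".join(_GT[int(d)] for d in genotypes.dosages[i])
            fh.write(
                f"{genotypes.chromosome[i]}\t{genotypes.position[i]}\t"
                f"{genotypes.snp_ids[i]}\t{genotypes.other_allele[i]}\t"
                f"{genotypes.effect_allele[i]}\t.\t.\t.\tGT\t{gts}\n"
            )


def _chrom_key(c: str) -> int:
    try:
        return int(c)
    except ValueError:
        return {"X": 23, "Y": 24, "MT": 25, "M": 25}.get(str(c).upper(), 99)


def read_vcf(path) -> GenotypeData:
    """Read a VCF (uncompressed or bgzipped) into effect-allele dosages.

    ALT allele counts become dosages; missing GT becomes -1; multiallelic
    sites are skipped with a warning.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, chroms, poss, eff, oth, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("%s: multiallelic site skipped", var.ID or f"{var.CHROM}:{var.POS}")
            continue
        # gts012: 0/1/2 = ALT count, 3 = unknown
        row = np.asarray(var.gt_types, dtype=np.int8)
        row[row == 3] = MISSING
        rows.append(row)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        eff.append(str(var.ALT[0]))
        oth.append(str(var.REF))
    vcf.close()
    if not rows:
        raise ParseError(f"{path}: no usable biallelic records")
    return GenotypeData(
        dosages=np.vstack(rows),
        snp_ids=snp_ids,
        chromosome=chroms,
        position=np.array(poss),
        effect_allele=eff,
        other_allele=oth,
        sample_ids=samples,
    )


def write_genotypes_tsv(genotypes: GenotypeData, path) -> None:
    """Dosage-matrix TSV: SNP metadata columns then one column per sample."""
    df = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chrom": genotypes.chromosome,
            "pos": genotypes.position,
            "effect_allele": genotypes.effect_allele,
            "other_allele": genotypes.other_allele,
        }
    )
    dos = pd.DataFrame(genotypes.dosages, columns=genotypes.sample_ids).astype(object)
    dos = dos.mask(dos == MISSING, "NA")
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    meta = ["snp_id", "chrom", "pos", "effect_allele", "other_allele"]
    missing_cols = set(meta) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    samples = [c for c in df.columns if c not in meta]
    dosages = df[samples].to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), MISSING, dosages).astype(np.int8)
    return GenotypeData(
        dosages=dosages,
        snp_ids=df["snp_id"].astype(str).tolist(),
        chromosome=df["chrom"].astype(str).tolist(),
        position=df["pos"].to_numpy(),
        effect_allele=df["effect_allele"].astype(str).tolist(),
        other_allele=df["other_allele"].astype(str).tolist(),
        sample_ids=samples,
    )


def read_genotypes(path, fmt: Optional[str] = None) -> GenotypeData:
    """Dispatch on format: 'vcf' or 'tsv' (inferred from the suffix by default)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValidationError(f"unknown genotype format {fmt!r}")


def write_covariates(genotypes: GenotypeData, path) -> None:
    if genotypes.status is None or genotypes.age_group is None:
        raise ValidationError("covariate output requires status and age_group")
    pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "status": genotypes.status,
            "age_group": genotypes.age_group,
        }
    ).to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "status", "age_group"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: covariates need columns {sorted(need)}")
    return df


def attach_phenotype(genotypes: GenotypeData, covariates: pd.DataFrame) -> GenotypeData:
    """Fill status/age_group from a covariate table, matching on sample_id."""
    cov = covariates.set_index("sample_id")
    missing = [s for s in genotypes.sample_ids if s not in cov.index]
    if missing:
        raise ValidationError(f"covariates missing for samples: {missing[:5]}...")
    genotypes.status = cov.loc[genotypes.sample_ids, "status"].to_numpy(dtype=np.int8)
    genotypes.age_group = cov.loc[genotypes.sample_ids, "age_group"].to_numpy(dtype=np.int8)
    return genotypes


def write_protein_matrix(matrix: ProteinMatrix, path) -> None:
    """Matrix TSV: first column protein_id, then one column per sample.

    Values are written on the log2 scale at full float precision (paired
    tissue columns are named '<pair>_tumor' / '<pair>_adjacent', which the
    reader parses back into pairing metadata).
    """
    if not matrix.is_log2:
        raise ValidationError("write log2-scale matrices (normalize first)")
    df = matrix.to_frame()
    df.insert(0, "protein_id", matrix.protein_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_protein_matrix(
    path,
    compartment: str,
    covariates: Optional[pd.DataFrame] = None,
    is_log2: bool = True,
) -> ProteinMatrix:
    """Read a matrix TSV; derive group labels from covariates (plasma) or
    tumor/adjacent column names (tissue)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "protein_id" not in df.columns:
        raise ParseError(f"{path}: first column must be protein_id")
    protein_ids = df["protein_id"].astype(str).tolist()
    samples = [c for c in df.columns if c != "protein_id"]
    values = df[samples].to_numpy(dtype=float)
    pair_id = None
    if compartment == "tissue":
        group, pair_id = [], []
        for s in samples:
            stem, _, kind = s.rpartition("_")
            if kind not in ("tumor", "adjacent") or not stem:
                raise ParseError(f"{path}: tissue column {s!r} not '<pair>_tumor/adjacent'")
            group.append(kind)
            pair_id.append(stem)
    elif compartment == "plasma":
        if covariates is None:
            raise ValidationError("plasma matrix needs a covariate table for group labels")
        cov = covariates.set_index("sample_id")
        group = ["case" if cov.loc[s, "status"] else "control" for s in samples]
    else:
        raise ValidationError(f"unknown compartment {compartment!r}")
    return ProteinMatrix(
        values=values,
        protein_ids=protein_ids,
        sample_ids=samples,
        group=group,
        compartment=compartment,
        pair_id=pair_id,
        is_log2=is_log2,
    )


def write_catalog(records: Sequence[PqtlRecord], path) -> None:
    pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "chrom": [r.chromosome for r in records],
            "pos": [r.position for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "protein_id": [r.target_protein_id for r in records],
            "gene": [r.gene for r in records],
            "beta": [r.beta for r in records],
            "p_value": [r.p_value for r in records],
            "source": [r.source for r in records],
        },
        columns=CATALOG_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[PqtlRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: catalog missing columns {sorted(missing)}")
    return [
        PqtlRecord(
            snp_id=str(r.snp_id),
            chromosome=str(r.chrom),
            position=int(r.pos),
            effect_allele=str(r.effect_allele),
            other_allele=str(r.other_allele),
            target_protein_id=str(r.protein_id),
            gene=str(r.gene),
            beta=float(r.beta),
            p_value=float(r.p_value),
            source=str(r.source),
        )
        for r in df.itertuples()
    ]


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"gene", "chrom", "tss"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: annotation needs columns {sorted(need)}")
    return df
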