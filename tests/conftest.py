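import numpy as np
import pytest

from pqtl_screen import simulate
from pqtl_screen.datatypes import GenotypeData, ProteinMatrix


@pytest.fixture
def two_locus_block():
    """Config with one 2-locus LD block (target r2 = 0.8) at MAF 0.3."""
    return simulate.SimulationConfig(
        loci=[
            simulate.LocusSpec("anchor", "1", 1000, "G", 0.3, "B1"),
            simulate.LocusSpec("partner", "1", 2000, "G", 0.3, "B1", target_r2=0.8),
        ],
        proteins=[],
        seed=1,
    )


@pytest.fixture
def small_cohort_config():
    """Desk-scale cohort: 200/200 samples, 4 loci, 12 proteins, 40 tissue pairs."""
    proteins = [
        simulate.ProteinSpec("SUP1", "GS1", "1", 1_000_000, "suppressor", -1.2, -1.2),
        simulate.ProteinSpec("SUP2", "GS2", "2", 2_000_000, "suppressor", -1.2, -1.2),
        simulate.ProteinSpec("ONC1", "GO1", "3", 3_000_000, "oncogenic", 1.2, 1.2),
    ] + [
        simulate.ProteinSpec(f"NUL{i}", f"GN{i}", str(4 + i), 4_000_000, "null")
        for i in range(9)
    ]
    log18 = float(np.log(1.8))
    loci = [
        simulate.LocusSpec("rsSUP1", "1", 1_050_000, "G", 0.3, "B1",
                           per_allele_log_or=log18, pqtl_beta=-0.5, target_protein="SUP1"),
        simulate.LocusSpec("rsSUP2", "2", 2_050_000, "G", 0.3, "B2",
                           per_allele_log_or=-log18, pqtl_beta=-0.5, target_protein="SUP2"),
        simulate.LocusSpec("rsONC1", "3", 3_050_000, "G", 0.3, "B3",
                           per_allele_log_or=log18, pqtl_beta=0.5, target_protein="ONC1"),
        simulate.LocusSpec("rsNULL", "5", 60_000_000, "C", 0.25, "B4"),
    ]
    return simulate.SimulationConfig(
        n_cases=200, n_controls=200, n_tissue_pairs=40,
        loci=loci, proteins=proteins, seed=11,
    )


def make_plasma(values, groups, protein_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    return ProteinMatrix(
        values=values,
        protein_ids=protein_ids,
        sample_ids=[f"S{i}" for i in range(values.shape[1])],
        group=list(groups),
        compartment="plasma",
    )


def make_tissue(tumor, adjacent, protein_ids=None):
    tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
    adjacent = np.atleast_2d(np.asarray(adjacent, dtype=float))
    n = tumor.shape[1]
    values = np.empty((tumor.shape[0], 2 * n))
    values[:, 0::2] = tumor
    values[:, 1::2] = adjacent
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    sample_ids, group, pair = [], [], []
    for i in range(n):
        sample_ids += [f"T{i}_tumor", f"T{i}_adjacent"]
        group += ["tumor", "adjacent"]
        pair += [f"T{i}", f"T{i}"]
    return ProteinMatrix(
        values=values, protein_ids=protein_ids, sample_ids=sample_ids,
        group=group, compartment="tissue", pair_id=pair,
    )


def make_genotypes(dosages, status=None, snp_ids=None, **kwargs):
    dosages = np.atleast_2d(np.asarray(dosages, dtype=np.int8))
    n_snp, n_smp = dosages.shape
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(n_snp)]
    defaults = dict(
        chromosome=["1"] * n_snp,
        position=np.arange(1, n_snp + 1) * 1000,
        effect_allele=["G"] * n_snp,
        other_allele=["A"] * n_snp,
        sample_ids=[f"S{i}" for i in range(n_smp)],
    )
    defaults.update(kwargs)
    g = GenotypeData(dosages=dosages, snp_ids=list(snp_ids), **defaults)
    if status is not None:
        g.status = np.asarray(status, dtype=np.int8)
    return g
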