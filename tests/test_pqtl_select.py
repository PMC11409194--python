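"""Catalog merge, cis/MAF filters, composite-LD r2 and greedy pruning."""

import numpy as np
import pandas as pd
import pytest

from pqtl_screen import pqtl_select, simulate
from pqtl_screen.datatypes import PqtlRecord
from pqtl_screen.exceptions import UndefinedLDError, ValidationError
from tests.conftest import make_genotypes


def rec(snp="rs1", protein="P1", p=1e-6, source="a", beta=0.5, chrom="1",
        pos=1_000_000, eff="G", oth="A", gene="G1"):
    return PqtlRecord(snp_id=snp, chromosome=chrom, position=pos,
                      effect_allele=eff, other_allele=oth,
                      target_protein_id=protein, gene=gene, beta=beta,
                      p_value=p, source=source)


class TestMergeCatalogs:
    def test_disjoint_union(self):
        a = [rec(snp=f"a{i}") for i in range(3)]
        b = [rec(snp=f"b{i}", source="b") for i in range(2)]
        assert len(pqtl_select.merge_catalogs([a, b], {"P1"})) == 5

    def test_dedupe_keeps_smaller_p_and_joins_sources(self):
        a = [rec(p=1e-5, source="iceland")]
        b = [rec(p=1e-8, source="finland")]
        (out,) = pqtl_select.merge_catalogs([a, b], {"P1"})
        assert out.p_value == 1e-8
        assert out.source == "finland+iceland"

    def test_restriction_excludes_other_proteins(self):
        out = pqtl_select.merge_catalogs([[rec(protein="OTHER")]], {"P1"})
        assert out == []

    def test_swapped_alleles_flip_beta(self):
        a = [rec(eff="G", oth="A", beta=0.5)]
        b = [rec(eff="A", oth="G", beta=0.3, p=1e-9, source="b")]
        (out,) = pqtl_select.merge_catalogs([a, b], {"P1"})
        assert out.effect_allele == "G"
        assert out.beta == -0.3  # best p record was the flipped one

    def test_irreconcilable_alleles_dropped(self):
        a = [rec(eff="G", oth="A")]
        b = [rec(eff="C", oth="T", p=1e-12, source="b")]
        (out,) = pqtl_select.merge_catalogs([a, b], {"P1"})
        assert out.source == "a"


class TestCisFilter:
    ANN = pd.DataFrame({"gene": ["G1"], "chrom": ["1"], "tss": [5_000_000]})

    @pytest.mark.parametrize(
        "pos,kept",
        [
            (5_000_000, True),       # at the TSS
            (6_000_000, True),       # exactly +window (closed interval)
            (6_000_001, False),      # one past the window
            (4_000_000, True),       # exactly -window
            (3_999_999, False),
        ],
    )
    def test_window_boundaries(self, pos, kept):
        out = pqtl_select.filter_cis([rec(pos=pos)], self.ANN, window=1_000_000)
        assert (len(out) == 1) is kept

    def test_other_chromosome_dropped(self):
        out = pqtl_select.filter_cis([rec(chrom="2", pos=5_000_000)], self.ANN)
        assert out == []

    def test_missing_gene_dropped(self):
        out = pqtl_select.filter_cis([rec(gene="UNKNOWN")], self.ANN)
        assert out == []


class TestMaf:
    def test_all_heterozygotes(self):
        g = make_genotypes([[1, 1, 1, 1]])
        (s,) = pqtl_select.compute_maf(g)
        assert s.maf == 0.5

    def test_hand_count(self):
        g = make_genotypes([[0, 0, 1, 2]])
        (s,) = pqtl_select.compute_maf(g)
        assert s.maf == 0.375
        assert s.effect_allele_freq == 0.375

    def test_monomorphic_and_missing(self):
        g = make_genotypes([[0, 0, 0], [-1, -1, -1]])
        mono, miss = pqtl_select.compute_maf(g)
        assert mono.maf == 0.0
        assert miss.n_nonmissing == 0

    def test_major_effect_allele_folds(self):
        g = make_genotypes([[2, 2, 2, 1]])
        (s,) = pqtl_select.compute_maf(g)
        assert s.effect_allele_freq == 0.875
        assert s.maf == 0.125

    @pytest.mark.parametrize("maf,kept", [(0.05, False), (0.051, True), (0.4, True)])
    def test_threshold_is_strict(self, maf, kept):
        from pqtl_screen.datatypes import SnpPanelStats

        stats = [SnpPanelStats("rs1", maf, maf, 100)]
        out = pqtl_select.filter_maf([rec()], stats, 0.05)
        assert (len(out) == 1) is kept

    def test_missing_stats_dropped(self):
        out = pqtl_select.filter_maf([rec()], [], 0.05)
        assert out == []


class TestLdR2:
    def test_self_correlation(self):
        a = np.array([0, 1, 2, 0, 1])
        assert pqtl_select.ld_r2(a, a) == 1.0

    def test_perfect_negative_correlation(self):
        assert pqtl_select.ld_r2([0, 1, 2, 0, 1], [2, 1, 0, 2, 1]) == pytest.approx(1.0)

    def test_hand_pearson(self):
        # cov = 0.5, var_a = 11/16, var_b = 0.5 (population moments) -> r2 = 8/11
        assert pqtl_select.ld_r2([0, 0, 1, 2], [0, 1, 1, 2]) == pytest.approx(8 / 11)

    def test_monomorphic_rejected(self):
        with pytest.raises(UndefinedLDError):
            pqtl_select.ld_r2([1, 1, 1, 1], [0, 1, 2, 0])

    def test_length_contract(self):
        with pytest.raises(ValidationError):
            pqtl_select.ld_r2([0, 1], [1, 0])


class TestLdPrune:
    def _panel_and_records(self):
        # v2 tracks v1 closely (r2 >= 0.8); v3 diverges (r2 < 0.8 with both)
        v1 = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 0, 1, 2])
        v2 = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 1, 1, 2])
        v3 = np.array([0, 0, 1, 1, 2, 1, 2, 0, 2, 0, 1, 2])
        panel = make_genotypes([v1, v2, v3], snp_ids=["s1", "s2", "s3"])
        r12 = pqtl_select.ld_r2(v1, v2)
        r13 = pqtl_select.ld_r2(v1, v3)
        r23 = pqtl_select.ld_r2(v2, v3)
        assert r12 >= 0.8 and r13 < 0.8 and r23 < 0.8
        records = [rec(snp="s1", p=1e-8, pos=1000), rec(snp="s2", p=1e-4, pos=2000),
                   rec(snp="s3", p=1e-2, pos=3000)]
        return panel, records

    def test_single_record_kept(self):
        panel, records = self._panel_and_records()
        assert pqtl_select.ld_prune(records[:1], panel) == records[:1]

    def test_correlated_pair_keeps_best_p(self):
        panel, records = self._panel_and_records()
        out = pqtl_select.ld_prune(records[:2], panel, 0.8)
        assert [r.snp_id for r in out] == ["s1"]

    def test_chain_keeps_first_and_third(self):
        panel, records = self._panel_and_records()
        out = pqtl_select.ld_prune(records, panel, 0.8)
        assert [r.snp_id for r in out] == ["s1", "s3"]

    def test_absent_snp_treated_unlinked(self):
        panel, records = self._panel_and_records()
        ghost = rec(snp="ghost", p=1e-9, pos=500)
        out = pqtl_select.ld_prune(records[:1] + [ghost], panel)
        assert {r.snp_id for r in out} == {"s1", "ghost"}

    def test_output_pairwise_r2_below_threshold(self):
        cfg = simulate.default_config(seed=3)
        panel = simulate.simulate_panel(cfg)
        records = simulate.catalog_records(cfg)
        out = pqtl_select.ld_prune(records, panel, 0.8)
        rows = {s: i for i, s in enumerate(panel.snp_ids)}
        kept = sorted({r.snp_id for r in out})
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                ca = out[[r.snp_id for r in out].index(a)].chromosome
                cb = out[[r.snp_id for r in out].index(b)].chromosome
                if ca == cb:
                    assert pqtl_select.ld_r2(
                        panel.dosages[rows[a]], panel.dosages[rows[b]]) < 0.8


class TestFilterAlgebra:
    ANN = pd.DataFrame({"gene": ["G1"], "chrom": ["1"], "tss": [1_000_000]})

    def _stats(self, mafs):
        from pqtl_screen.datatypes import SnpPanelStats

        return [SnpPanelStats(f"r{i}", m, m, 100) for i, m in enumerate(mafs)]

    def test_cis_and_maf_commute(self):
        records = [rec(snp=f"r{i}", pos=900_000 + i * 600_000) for i in range(4)]
        stats = self._stats([0.01, 0.2, 0.3, 0.04])
        a = pqtl_select.filter_maf(
            pqtl_select.filter_cis(records, self.ANN), stats, 0.05)
        b = pqtl_select.filter_cis(
            pqtl_select.filter_maf(records, stats, 0.05), self.ANN)
        assert a == b

    def test_monotone_in_thresholds(self):
        records = [rec(snp=f"r{i}", pos=500_000 + i * 400_000) for i in range(5)]
        stats = self._stats([0.02, 0.06, 0.10, 0.30, 0.45])
        narrow = {r.snp_id for r in pqtl_select.filter_cis(records, self.ANN, 500_000)}
        wide = {r.snp_id for r in pqtl_select.filter_cis(records, self.ANN, 1_000_000)}
        assert narrow <= wide
        strict = {r.snp_id for r in pqtl_select.filter_maf(records, stats, 0.10)}
        lax = {r.snp_id for r in pqtl_select.filter_maf(records, stats, 0.05)}
        assert strict <= lax
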