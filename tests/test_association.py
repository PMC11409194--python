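"""Association contracts: contingency counts, cross-product ORs against
published worked examples, the IRLS fit against closed forms and an
independent statsmodels oracle, and the multi-model scan."""

import numpy as np
import pytest
from scipy import stats

from pqtl_screen import association, datasets
from pqtl_screen.datatypes import ContingencyTable
from pqtl_screen.exceptions import SeparationError, ValidationError
from tests.conftest import make_genotypes


class TestGenotypeCounts:
    def test_direct_tally(self):
        g = make_genotypes([[0, 1, 1, 2]], status=[1, 1, 0, 0])
        (t,) = association.genotype_counts(g)
        assert t.cases == (1, 1, 0)
        assert t.controls == (0, 1, 1)

    def test_counts_conserve_cohort_sizes(self):
        from pqtl_screen import simulate

        cfg = simulate.default_config(seed=1)
        cfg.n_cases, cfg.n_controls = 150, 180
        g = simulate.simulate_phenotype(simulate.simulate_genotypes(cfg), cfg)
        for t in association.genotype_counts(g):
            assert t.n_cases == 150 and t.n_controls == 180

    def test_brute_force_recount(self):
        rng = np.random.default_rng(5)
        dosages = rng.integers(0, 3, size=(3, 50))
        dosages[0, :4] = -1  # some missing calls
        status = rng.integers(0, 2, size=50)
        g = make_genotypes(dosages, status=status)
        tables = association.genotype_counts(g)
        for i, t in enumerate(tables):
            for geno in range(3):
                n_case = sum(
                    1 for j in range(50)
                    if dosages[i, j] == geno and status[j] == 1
                )
                n_ctrl = sum(
                    1 for j in range(50)
                    if dosages[i, j] == geno and status[j] == 0
                )
                assert t.cases[geno] == n_case
                assert t.controls[geno] == n_ctrl
        assert tables[0].n_missing == 4

    def test_all_missing_snp_excluded(self):
        g = make_genotypes([[-1, -1], [0, 1]], status=[1, 0])
        tables = association.genotype_counts(g)
        assert [t.snp_id for t in tables] == ["snp1"]


class TestCrudeOr:
    def test_published_hom_contrast(self):
        # GG vs AA for the COL6A3 variant: (285*1829)/(354*1802)
        table = datasets.flcca_tables()[0]
        r = association.crude_or(table, "hom_vs_ref")
        assert round(r.or_estimate, 2) == 0.82
        assert round(r.ci_low, 2) == 0.69
        assert round(r.ci_high, 2) == 0.97

    def test_published_dominant_contrast(self):
        table = next(t for t in datasets.flcca_tables() if t.snp_id == "rs7683000")
        r = association.crude_or(table, "dominant")
        assert r.or_estimate == pytest.approx((1426 * 2264) / (2027 * 1446))
        assert round(r.or_estimate, 2) == 1.10

    def test_symmetric_table_is_null(self):
        t = ContingencyTable("s", (50, 30, 0), (50, 30, 0))
        r = association.crude_or(t, "het_vs_ref")
        assert r.or_estimate == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        t = ContingencyTable("s", (10, 5, 0), (10, 5, 3))
        r = association.crude_or(t, "hom_vs_ref")
        assert r.continuity_corrected
        expected = (0.5 * 10.5) / (3.5 * 10.5)
        assert r.or_estimate == pytest.approx(expected)

    def test_wald_ci_formula(self):
        t = ContingencyTable("s", (100, 40, 0), (120, 30, 0))
        r = association.crude_or(t, "het_vs_ref")
        se = np.sqrt(1 / 40 + 1 / 30 + 1 / 100 + 1 / 120)
        lo = np.exp(np.log(r.or_estimate) - 1.959963984540054 * se)
        assert r.ci_low == pytest.approx(lo, rel=1e-12)


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70, dtype=float)
        X = np.ones((100, 1))
        fit = association.logistic_fit(X, y)
        assert fit.coef[0] == pytest.approx(np.log(30 / 70), rel=1e-10)

    def test_binary_exposure_equals_log_crude_or(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b, c, d = rng.integers(5, 200, size=4)
            x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
            y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
            X = np.column_stack([np.ones_like(x), x])
            fit = association.logistic_fit(X, y)
            assert fit.coef[1] == pytest.approx(np.log((a * d) / (b * c)), rel=1e-10)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        X = np.column_stack([np.ones(300), rng.normal(size=300), rng.integers(0, 3, 300)])
        eta = 0.3 + 0.5 * X[:, 1] - 0.4 * X[:, 2]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = association.logistic_fit(X, y)
        sm_fit = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coef, sm_fit.params, rtol=1e-6)
        assert np.allclose(fit.se, sm_fit.bse, rtol=1e-4)

    def test_separation_detected(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(SeparationError):
            association.logistic_fit(np.column_stack([np.ones_like(x), x]), y)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(40), np.arange(40.0), np.arange(40.0)])
        y = np.tile([0.0, 1.0], 20)
        with pytest.raises(ValidationError, match="rank"):
            association.logistic_fit(X, y)


class TestScan:
    def test_encoding_identity_with_crude_or(self):
        # unadjusted logistic on the reconstructed cohort must reproduce
        # every cross-product OR (saturated-model identity)
        table = datasets.flcca_tables()[1]
        cohort = datasets.table_to_genotypes(table)
        results, _ = association.association_scan(cohort)
        by_model = {r.model: r for r in results}
        for model in ("het_vs_ref", "hom_vs_ref", "dominant", "recessive"):
            crude = association.crude_or(table, model)
            assert by_model[model].or_estimate == pytest.approx(
                crude.or_estimate, rel=1e-8)

    def test_additive_or_between_genotype_ors(self):
        # exactly log-additive penetrance (expected counts at n=100000):
        # the additive per-allele OR lies between the het and hom ORs
        n, p = 100000, 0.3
        geno_counts = np.round(n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]))
        case_prob = 1 / (1 + np.exp(-(-0.5 + np.log(1.4) * np.arange(3))))
        cases = np.round(geno_counts * case_prob).astype(int)
        ctrls = (geno_counts - cases).astype(int)
        g = np.concatenate([np.full(c + k, i) for i, (c, k) in enumerate(zip(cases, ctrls))])
        y = np.concatenate([
            np.concatenate([np.ones(c), np.zeros(k)]) for c, k in zip(cases, ctrls)
        ]).astype(int)
        geno = make_genotypes(g.reshape(1, -1), status=y)
        results, _ = association.association_scan(geno)
        by_model = {r.model: r.or_estimate for r in results}
        tol = 1.002  # count rounding
        assert by_model["het_vs_ref"] / tol <= by_model["additive"]
        assert by_model["additive"] <= by_model["hom_vs_ref"] * tol

    def test_separation_skipped_scan_continues(self):
        sep = [0] * 10 + [2] * 10          # dosage perfectly tracks status
        ok = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0] * 2
        status = [0] * 10 + [1] * 10
        g = make_genotypes([sep, ok], status=status, snp_ids=["bad", "good"])
        results, flags = association.association_scan(g, models=["dominant", "additive"])
        assert {r.snp_id for r in results} == {"good"}
        assert "bad" not in flags

    def test_age_adjustment_changes_estimate(self):
        from pqtl_screen import simulate

        cfg = simulate.default_config(seed=21)
        cfg.n_cases = cfg.n_controls = 400
        cfg.age_effect = 0.7
        g = simulate.simulate_phenotype(simulate.simulate_genotypes(cfg), cfg)
        crude, _ = association.association_scan(g, models=["additive"])
        adj, _ = association.association_scan(g, models=["additive"], adjust=["age_group"])
        assert adj[0].adjusted and not crude[0].adjusted
        assert adj[0].covariates == ("age_group",)

    def test_null_ci_coverage(self):
        # 95% Wald CI from crude cross-products covers OR=1 for ~95% of
        # null 2x2 tables at 500/500
        rng = np.random.default_rng(17)
        cover = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.binomial(500, 0.3)
            b = rng.binomial(500, 0.3)
            t = ContingencyTable("s", (500 - a, a, 0), (500 - b, b, 0))
            r = association.crude_or(t, "het_vs_ref")
            cover += r.ci_low <= 1.0 <= r.ci_high
        assert 0.93 <= cover / n_rep <= 0.97
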