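"""Genetic-model coding, logistic IRLS, BH-FDR and heterogeneity statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sevariant.association import (
    HeterogeneityStats,
    association_scan,
    bh_fdr,
    cochran_q,
    code_genotype,
    counts_to_arrays,
    fit_logistic,
    or_from_2x2,
    stratified_analysis,
)
from sevariant.variant_qc import GenotypeMatrix


class TestCodeGenotype:
    calls = np.array([0, 1, 2])

    def test_model_definitions(self):
        add, _, _ = code_genotype(self.calls, "additive")
        dom, _, _ = code_genotype(self.calls, "dominant")
        rec, _, _ = code_genotype(self.calls, "recessive")
        cod, names, _ = code_genotype(self.calls, "codominant")
        assert add.ravel().tolist() == [0, 1, 2]
        assert dom.ravel().tolist() == [0, 1, 1]
        assert rec.ravel().tolist() == [0, 0, 1]
        assert cod[:, 0].tolist() == [0, 1, 0] and cod[:, 1].tolist() == [0, 0, 1]
        assert names == ["het", "hom_alt"]

    def test_missing_samples_masked(self):
        X, _, mask = code_genotype(np.array([0, -1, 2]), "additive")
        assert mask.tolist() == [True, False, True]
        assert X.ravel().tolist() == [0, 2]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            code_genotype(self.calls, "overdominant")


def _binary_design(a, b, c, d):
    """2x2 table: (exposed cases, unexposed cases, exposed controls, unexposed controls)."""
    y = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    x = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_matches_2x2_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b, c, d = rng.integers(1, 400, size=4)
            y, X = _binary_design(a, b, c, d)
            fit = fit_logistic(y, X)
            or_cf, se_cf = or_from_2x2(a, b, c, d)
            assert np.exp(fit.beta[1]) == pytest.approx(or_cf, abs=1e-8 * or_cf)
            assert fit.se[1] == pytest.approx(se_cf, abs=1e-8)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 400
        X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n), rng.normal(size=n)])
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.3 + 0.4 * X[:, 1] + 0.2 * X[:, 2]))))
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        assert ours.beta == pytest.approx(ref.params, abs=1e-6)
        assert ours.se == pytest.approx(ref.bse, abs=1e-6)

    def test_null_predictor_beta_near_zero(self):
        rng = np.random.default_rng(12)
        n = 2000
        X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n)])
        y = rng.binomial(1, 0.5, n)
        fit = fit_logistic(y, X)
        assert abs(fit.beta[1] / fit.se[1]) < 4

    def test_separation_flagged(self):
        y = np.array([0.0] * 10 + [1.0] * 10)
        X = np.column_stack([np.ones(20), y])  # perfect separation
        fit = fit_logistic(y, X)
        assert not fit.converged

    def test_singular_design_names_columns(self):
        n = 50
        x = np.random.default_rng(0).normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(np.random.default_rng(1).binomial(1, 0.5, n), X,
                         ["intercept", "x", "x_twice"])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_logistic(np.array([1.0]), np.ones((1, 2)))


class TestOrFrom2x2:
    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            or_from_2x2(0, 5, 5, 5)


class TestBhFdr:
    def test_small_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_capped(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-8, 1, size=200)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels_when_m_equals_len(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(1e-6, 1, size=97)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert bh_fdr(p) == pytest.approx(ref, abs=1e-12)

    def test_stable_under_input_order(self):
        p = [0.04, 0.001, 0.2, 0.001, 0.9]
        adj = bh_fdr(p)
        perm = [4, 2, 0, 3, 1]
        assert bh_fdr([p[i] for i in perm]) == pytest.approx([adj[i] for i in perm])

    def test_external_m_scales_the_adjustment(self):
        assert bh_fdr([7.61e-5], m=513)[0] == pytest.approx(513 * 7.61e-5)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError, match="m="):
            bh_fdr([0.1, 0.2], m=1)


class TestCochranQ:
    def test_identical_strata_no_heterogeneity(self):
        het = cochran_q([0.3, 0.3], [0.1, 0.1])
        assert het.q == pytest.approx(0.0) and het.i2 == 0.0

    def test_hand_computed_example(self):
        # w = 100 each; weighted mean 1/3; Q = 100*(2*(0.2-1/3)^2 + (0.6-1/3)^2)
        het = cochran_q([0.2, 0.2, 0.6], [0.1, 0.1, 0.1])
        assert het.q == pytest.approx(32 / 3, rel=1e-12)
        assert het.df == 2
        assert het.i2 == pytest.approx(81.25)
        assert het.p_het == pytest.approx(sps.chi2.sf(32 / 3, 2))

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError, match="strata"):
            cochran_q([0.2], [0.1])

    def test_invariant_to_stratum_order(self):
        b, s = [0.1, 0.5, -0.2], [0.2, 0.1, 0.3]
        assert cochran_q(b, s).q == pytest.approx(cochran_q(b[::-1], s[::-1]).q)

    def test_i2_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            het = cochran_q(rng.normal(size=4), rng.uniform(0.05, 1, size=4))
            assert 0 <= het.i2 <= 100


def _study(rng, n=600, maf=0.3, beta=0.0):
    g = rng.binomial(2, maf, size=n).astype(np.int8)
    eta = -0.2 + beta * g
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    variants = pd.DataFrame({"id": ["v0"], "chrom": "chr1", "pos": [100], "ref": "A", "alt": "G"})
    gm = GenotypeMatrix([f"s{i}" for i in range(n)], variants, g[None, :])
    phen = pd.DataFrame(
        {"sample": gm.samples, "status": np.where(y, "case", "control"),
         "age": rng.normal(65, 7, n), "bmi": rng.normal(27, 4, n),
         "smoking": rng.choice(["never", "ever", "current"], n),
         "family_history": rng.integers(0, 2, n),
         "grp": rng.choice(["a", "b"], n)}
    )
    return gm, phen


class TestAssociationScan:
    def test_codominant_missing_class_reported_undefined(self):
        rng = np.random.default_rng(3)
        gm, phen = _study(rng)
        gm.calls[gm.calls == 2] = 1  # remove the hom-alt class entirely
        res = association_scan(gm, phen, model="codominant")
        hom = res[res["term"] == "hom_alt"].iloc[0]
        het = res[res["term"] == "het"].iloc[0]
        assert np.isnan(hom["or_"]) and np.isfinite(het["or_"])

    def test_adjusted_run_produces_finite_estimates(self):
        rng = np.random.default_rng(5)
        gm, phen = _study(rng, beta=0.4)
        res = association_scan(gm, phen, model="additive",
                               covariates=("age", "bmi", "smoking", "family_history"))
        assert np.isfinite(res["beta"]).all()
        assert res["ci_low"].iloc[0] < res["or_"].iloc[0] < res["ci_high"].iloc[0]

    def test_table_counts_roundtrip_through_arrays(self):
        y, g = counts_to_arrays([10, 5, 2], [8, 6, 1])
        assert len(y) == 32 and (g == 1).sum() == 11


class TestStratifiedAnalysis:
    def test_population_strata_and_heterogeneity(self):
        rng = np.random.default_rng(7)
        gm, phen = _study(rng, n=1200, beta=0.3)
        table, het = stratified_analysis(gm, phen, "v0", "grp", model="dominant")
        assert set(table["stratum"]) == {"a", "b"}
        assert isinstance(het, HeterogeneityStats)
        assert het.df == 1

    def test_case_only_subgroups_share_controls(self):
        rng = np.random.default_rng(9)
        gm, phen = _study(rng, n=1500, beta=0.3)
        phen["gleason"] = np.where(phen["status"] == "case",
                                   rng.choice(["7", "<7"], len(phen)), None)
        table, _ = stratified_analysis(gm, phen, "v0", "gleason", model="dominant",
                                       case_only=True)
        n_controls = (phen["status"] == "control").sum()
        assert (table["n_controls"] == n_controls).all()

    def test_single_stratum_rejected(self):
        rng = np.random.default_rng(10)
        gm, phen = _study(rng)
        phen["grp"] = "only"
        with pytest.raises(ValueError, match="strata"):
            stratified_analysis(gm, phen, "v0", "grp")
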