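import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from awmnet import gwas
from awmnet.errors import DataError, NumericalError
from awmnet.panel import GenotypePanel
from awmnet.simulate import SimConfig, gen_genotypes, gen_microbiome
from awmnet.phenotypes import build_phenotypes

from oracles import ols_slope_after_covariates


def _panel(dosages, bp_step=10000):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    snp_map = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chrom": "1",
         "bp": np.arange(1, m + 1) * bp_step}
    )
    return GenotypePanel(dosages, snp_map)


class TestSnpFilter:
    def test_maf_boundary_kept_strict_below_removed(self):
        n = 20
        at_5pct = np.zeros(n)
        at_5pct[:2] = 1.0                      # MAF exactly 0.05
        below = np.zeros(n)
        below[0] = 1.0                         # MAF 0.025
        mono = np.zeros(n)                     # MAF 0
        keep_all = np.tile([0, 1, 2, 1], 5).astype(float)
        p = _panel(np.column_stack([at_5pct, below, mono, keep_all]))
        out = gwas.filter_snps(p, min_maf=0.05, max_missing=0.10)
        assert list(out.snp_map["snp_id"]) == ["s0", "s3"]

    def test_missingness_boundary_kept(self):
        n = 20
        col = np.tile([0, 1, 2, 1], 5).astype(float)
        exactly_10 = col.copy(); exactly_10[:2] = np.nan
        above_10 = col.copy(); above_10[:3] = np.nan
        p = _panel(np.column_stack([exactly_10, above_10]))
        out = gwas.filter_snps(p, min_maf=0.0, max_missing=0.10)
        assert list(out.snp_map["snp_id"]) == ["s0"]

    def test_all_removed_raises(self):
        p = _panel(np.zeros((10, 3)))
        with pytest.raises(DataError):
            gwas.filter_snps(p)


class TestGrm:
    def test_identical_individuals_identical_rows(self, tiny_panel):
        filt = gwas.filter_snps(tiny_panel)
        dup = GenotypePanel(
            np.vstack([filt.dosages, filt.dosages[:1]]), filt.snp_map
        )
        g = gwas.compute_grm(dup)
        np.testing.assert_allclose(g[0, 1:-1], g[-1, 1:-1], atol=1e-12)

    def test_offdiagonal_matches_direct_product(self, tiny_panel):
        filt = gwas.filter_snps(tiny_panel)
        g = gwas.compute_grm(filt)
        x = filt.imputed_dosages()
        p = filt.allele_frequency()
        w = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
        direct = w @ w.T / filt.n_snps
        off = ~np.eye(len(g), dtype=bool)
        np.testing.assert_allclose(g[off], direct[off], atol=1e-12)
        assert np.allclose(g, g.T)

    def test_monomorphic_rejected(self):
        p = _panel(np.column_stack([np.zeros(10), np.ones(10)]))
        with pytest.raises(NumericalError):
            gwas.compute_grm(p)

    def test_hwe_mean_diagonal_near_one(self):
        cfg = SimConfig(n_individuals=200, n_snps=5000, missing_rate=0.0, seed=21)
        g = gwas.compute_grm(gen_genotypes(cfg))
        assert abs(np.mean(np.diag(g)) - 1.0) < 0.05


class TestNullModel:
    def test_no_genetic_variance_hits_boundary_and_matches_ols(self):
        # pure-noise phenotype at a sample size where the REML estimate of
        # the variance ratio collapses to the boundary
        cfg = SimConfig(n_individuals=400, n_snps=2000, missing_rate=0.02,
                        seed=11)
        filt = gwas.filter_snps(gen_genotypes(cfg))
        grm = gwas.compute_grm(filt)
        rng = np.random.default_rng(5)
        n = filt.n_individuals
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n),
                            "batch": rng.integers(0, 7, n)})
        y = rng.standard_normal(n)
        x = gwas.covariate_design(cov)
        fit = gwas.fit_null_model(y, x, grm)
        assert fit.at_boundary and fit.sigma_u2 == 0.0
        res = gwas.snp_scan(filt, y, x, fit)
        slopes = ols_slope_after_covariates(y, filt.imputed_dosages(), x)
        np.testing.assert_allclose(res["effect"], slopes, atol=1e-6)

    def test_reml_optimum_beats_endpoints(self, tiny_panel):
        rng = np.random.default_rng(4)
        filt = gwas.filter_snps(tiny_panel)
        grm = gwas.compute_grm(filt)
        n = filt.n_individuals
        x = np.ones((n, 1))
        d, u = gwas.grm_eigendecomposition(grm)
        y = (u * np.sqrt(d)) @ rng.standard_normal(n) + rng.standard_normal(n)
        fit = gwas.fit_null_model(y, x, grm, eig=(d, u))
        from awmnet.gwas import _reml_neg_loglik
        for endpoint in (-8.0, 8.0):
            assert fit.loglik >= -_reml_neg_loglik(endpoint, u.T @ y, u.T @ x, d) - 1e-9


class TestScan:
    def test_identity_grm_equals_ols_slope(self, tiny_panel):
        rng = np.random.default_rng(9)
        filt = gwas.filter_snps(tiny_panel)
        n = filt.n_individuals
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n)})
        x = gwas.covariate_design(cov)
        y = rng.standard_normal(n)
        fit = gwas.fit_null_model(y, x, np.eye(n))
        res = gwas.snp_scan(filt, y, x, fit)
        slopes = ols_slope_after_covariates(y, filt.imputed_dosages(), x)
        np.testing.assert_allclose(res["effect"], slopes, atol=1e-9)

    def test_constant_snp_flagged_missing(self):
        dos = np.column_stack([np.tile([0, 1, 2, 1], 5), np.full(20, 1.0)])
        p = _panel(dos)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(20)
        x = np.ones((20, 1))
        fit = gwas.fit_null_model(y, x, np.eye(20))
        res = gwas.snp_scan(p, y, x, fit)
        assert np.isnan(res.loc[1, "p"])
        assert np.isfinite(res.loc[0, "p"])

    def test_null_pvalues_uniform_through_full_generator(self):
        # no planted effects, no heritability: the scan's p-values should be
        # uniform; independent markers keep the KS test honest
        cfg = SimConfig(n_individuals=250, n_snps=2000, ld_block_size=1,
                        h2=0.0, n_causal_per_taxon=0, n_regulator_snps=0,
                        n_bacteria=8, n_protists=3, seed=17)
        panel = gen_genotypes(cfg)
        counts, cov, _ = gen_microbiome(panel, cfg)
        phen = build_phenotypes(counts, cov, seed=1)
        filt = gwas.filter_snps(panel)
        res = gwas.run_gwas(filt, phen.values[["B_BactGenus01"]],
                            cov.loc[phen.values.index, ["sex", "batch"]])
        p = res.pvalues["B_BactGenus01"].dropna()
        assert kstest(p, "uniform").pvalue > 0.01


class TestFdr:
    @pytest.mark.parametrize(
        "a, expected_pct",
        [(3836, 53.13), (3803, 53.64), (3644, 56.21)],
    )
    def test_reference_values(self, a, expected_pct):
        assert 100 * gwas.fdr(0.05, a, 42562) == pytest.approx(expected_pct,
                                                               abs=0.005)

    def test_degenerate_cases(self):
        assert gwas.fdr(0.05, int(0.05 * 42562), 42562) == pytest.approx(
            1.0, rel=1e-3
        )
        assert gwas.fdr(0.05, 42562, 42562) == 0.0
        with pytest.raises(DataError):
            gwas.fdr(0.05, 0, 1000)
        with pytest.raises(DataError):
            gwas.fdr(1.5, 10, 1000)

    @given(st.integers(min_value=1, max_value=9999))
    @settings(max_examples=60, deadline=None)
    def test_decreasing_in_significant_count(self, a):
        t = 10000
        lo = gwas.fdr(0.05, a, t)
        assert lo >= 0.0
        if a < t:
            assert gwas.fdr(0.05, a + 1, t) < lo


class TestStandardize:
    def test_two_effects_closed_form(self):
        eff = pd.DataFrame({"y": [1.0, -1.0]}, index=["a", "b"])
        res = _make(eff)
        np.testing.assert_allclose(res.zscores["y"], [0.70710678, -0.70710678])

    def test_unit_sd_and_signflip_commutes(self):
        rng = np.random.default_rng(12)
        eff = pd.DataFrame({"y": rng.standard_normal(50)})
        res = _make(eff)
        assert res.zscores["y"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        flipped = _make(-eff)
        np.testing.assert_allclose(flipped.zscores["y"], -res.zscores["y"])

    def test_zero_sd_raises(self):
        eff = pd.DataFrame({"y": [2.0, 2.0, 2.0]})
        with pytest.raises(NumericalError):
            _make(eff)


def _make(effects: pd.DataFrame):
    from conftest import make_resultset

    pvals = effects.abs() * 0 + 0.5
    return make_resultset(pvals, effects=effects)


class TestSummary:
    def test_fdr_summary_self_consistent(self, tiny_panel):
        rng = np.random.default_rng(2)
        filt = gwas.filter_snps(tiny_panel)
        n = filt.n_individuals
        cov = pd.DataFrame({"sex": rng.integers(0, 2, n)})
        phen = pd.DataFrame({"y1": rng.standard_normal(n),
                             "y2": rng.standard_normal(n)})
        res = gwas.run_gwas(filt, phen, cov)
        summary = gwas.fdr_summary(res)
        t = len(res.snp_map)
        for _, row in summary.iterrows():
            a = row["N_p0.05"]
            if a > 0:
                assert row["FDR%_p0.05"] == pytest.approx(
                    100 * gwas.fdr(0.05, int(a), t)
                )
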