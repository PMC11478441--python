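"""Logistic engine: closed-form oracles, Wald/LRT behaviour, GWAS scan."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gmdrprs as g
from gmdrprs.errors import ConvergenceError, ParameterError


def _two_by_two(a, b, c, d):
    """y/x data for a 2x2 table: a exposed cases, b exposed controls,
    c unexposed cases, d unexposed controls."""
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, pd.DataFrame({"const": np.ones_like(x), "x": x})


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = pd.DataFrame({"const": np.ones(100)})
        fit = g.fit_logistic(y, X)
        assert fit.params["const"] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    @pytest.mark.parametrize("cells", [
        (10, 90, 5, 95), (20, 30, 10, 40), (1, 9, 3, 7), (50, 50, 25, 75),
        (7, 3, 2, 8), (100, 400, 30, 470),
    ])
    def test_two_by_two_cross_product_exact(self, cells):
        a, b, c, d = cells
        y, X = _two_by_two(a, b, c, d)
        fit = g.fit_logistic(y, X)
        assert math.exp(fit.params["x"]) == pytest.approx(a * d / (b * c), abs=1e-8)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.binomial(2, 0.3, n).astype(float)
        eta = -2.0 + math.log(3) * x
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        fit = g.fit_logistic(y, pd.DataFrame({"const": np.ones(n), "x": x}))
        assert math.exp(fit.params["x"]) == pytest.approx(3.0, rel=0.1)

    def test_separation_flagged_not_silent(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()  # perfect separation
        fit = g.fit_logistic(y, pd.DataFrame({"const": np.ones(40), "x": x}))
        assert not fit.converged
        with pytest.raises(ConvergenceError):
            g.wald_or(fit, "x")

    def test_rank_deficiency_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.arange(20.0)
        X = pd.DataFrame({"const": 1.0, "x": x, "x2": 2 * x})
        with pytest.raises(ParameterError):
            g.fit_logistic(y, X)


class TestWaldOR:
    def test_null_beta_ci(self):
        fit = g.GLMFit(params=pd.Series({"x": 0.0}), bse=pd.Series({"x": 0.1}),
                       loglik=-1.0, converged=True, n_iter=3, nobs=100)
        res = g.wald_or(fit, "x")
        assert res.or_point == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(math.exp(-0.196), abs=1e-3)
        assert res.ci_high == pytest.approx(math.exp(0.196), abs=1e-3)

    def test_ci_collapses_as_se_vanishes(self):
        fit = g.GLMFit(params=pd.Series({"x": math.log(2)}), bse=pd.Series({"x": 1e-12}),
                       loglik=-1.0, converged=True, n_iter=3, nobs=100)
        res = g.wald_or(fit, "x")
        assert res.ci_low == pytest.approx(2.0, rel=1e-6)
        assert res.ci_high == pytest.approx(2.0, rel=1e-6)

    def test_wald_p_agrees_with_score_test_oracle(self):
        """Order-of-magnitude agreement with the chi-square score test on
        the same 2x2 table."""
        a, b, c, d = 30, 70, 15, 85
        y, X = _two_by_two(a, b, c, d)
        res = g.wald_or(g.fit_logistic(y, X), "x")
        chi2, p_score = stats.chi2_contingency(np.array([[a, b], [c, d]]),
                                               correction=False)[:2]
        assert 0.1 < res.p / p_score < 10


class TestLRT:
    def test_identical_models_p_one(self):
        y = np.r_[np.ones(20), np.zeros(30)]
        X = pd.DataFrame({"const": np.ones(50)})
        fit = g.fit_logistic(y, X)
        assert g.lrt(fit, fit, df=1) == pytest.approx(1.0)

    def test_nesting_violation_rejected(self):
        f1 = g.GLMFit(pd.Series({"c": 0.0}), pd.Series({"c": 1.0}), -10.0, True, 1, 10)
        f2 = g.GLMFit(pd.Series({"c": 0.0}), pd.Series({"c": 1.0}), -5.0, True, 1, 10)
        with pytest.raises(ParameterError):
            g.lrt(f1, f2, df=1)  # "full" fits worse than "reduced"

    def test_null_pvalues_uniform(self):
        """LRT p for an unrelated covariate is ~U(0,1) under the null."""
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(300):
            n = 400
            y = rng.binomial(1, 0.3, n).astype(float)
            z = rng.normal(size=n)
            X0 = pd.DataFrame({"const": np.ones(n)})
            X1 = X0.assign(z=z)
            pvals.append(g.lrt(g.fit_logistic(y, X1), g.fit_logistic(y, X0), df=1))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_strong_effect(self):
        rng = np.random.default_rng(10)
        n = 10_000
        z = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + 0.5 * z))))
        X0 = pd.DataFrame({"const": np.ones(n)})
        X1 = X0.assign(z=z)
        assert g.lrt(g.fit_logistic(y, X1), g.fit_logistic(y, X0), df=1) < 1e-6


class TestGWASScan:
    def test_null_scan_pass_count(self, null_cohort):
        res = g.gwas_scan(null_cohort.genotypes, null_cohort.outcome, alpha=5e-4)
        # expected passes = 20 * 5e-4 = 0.01
        assert int(res["pass"].sum()) <= 2

    def test_planted_effect_flagged(self):
        rng_seed = 21
        specs = [g.SNPSpec(id=f"s{i}", maf=0.3) for i in range(5)]
        model = g.EffectModel(intercept=math.log(0.1 / 0.9),
                              additive_betas={"s2": math.log(1.6)})
        ds = g.simulate_cohort(specs, 20_000, model, seed=rng_seed)
        res = g.gwas_scan(ds.genotypes, ds.outcome, alpha=5e-4)
        assert bool(res.loc["s2", "pass"])
        assert res.loc["s2", "or"] == pytest.approx(1.6, rel=0.15)

    def test_confounded_snp_attenuated_by_adjustment(self):
        """A SNP whose association runs through a correlated covariate
        shrinks toward the null once the covariate is adjusted."""
        rng = np.random.default_rng(22)
        n = 20_000
        gdos = rng.binomial(2, 0.3, n).astype(float)
        conf = gdos + rng.normal(0, 1.0, n)          # covariate correlated with SNP
        y = rng.binomial(1, 1 / (1 + np.exp(-(-2.0 + 0.8 * conf))))
        gm = g.GenotypeMatrix(gdos[:, None], ["s"], [f"S{i}" for i in range(n)],
                              g.datatypes.default_snp_meta(["s"]))
        crude = g.gwas_scan(gm, y)
        adj = g.gwas_scan(gm, y, pd.DataFrame({"conf": conf}))
        assert abs(math.log(adj.loc["s", "or"])) < abs(math.log(crude.loc["s", "or"]))

    def test_invariant_to_row_and_snp_permutation(self):
        rng = np.random.default_rng(23)
        specs = [g.SNPSpec(id=f"s{i}", maf=0.3) for i in range(4)]
        ds = g.simulate_cohort(specs, 1500, g.EffectModel(intercept=-1.0), seed=3)
        base = g.gwas_scan(ds.genotypes, ds.outcome)
        perm = rng.permutation(ds.genotypes.n_samples)
        gm_p = ds.genotypes.subset(sample_idx=perm)
        shuffled_snps = gm_p.subset(snp_ids=["s2", "s0", "s3", "s1"])
        res_p = g.gwas_scan(shuffled_snps, ds.outcome[perm])
        for s in ["s0", "s1", "s2", "s3"]:
            assert res_p.loc[s, "p"] == pytest.approx(base.loc[s, "p"], rel=1e-6)

    def test_monomorphic_skipped_with_reason(self):
        n = 200
        y = np.r_[np.ones(50), np.zeros(150)]
        gm = g.GenotypeMatrix(np.zeros((n, 1)), ["mono"], [f"S{i}" for i in range(n)],
                              g.datatypes.default_snp_meta(["mono"]))
        res = g.gwas_scan(gm, y)
        assert res.loc["mono", "note"] == "monomorphic"
        assert np.isnan(res.loc["mono", "or"])
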