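"""GMDR engine: score residuals, cell labelling, balanced accuracy,
cross-validation, exact signed-rank test, and the exhaustive search."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gmdrprs as g
from gmdrprs.errors import BudgetExceededError, UndefinedStatisticError


class TestScoreResiduals:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        s = g.score_residuals(y)
        assert np.allclose(s[:30], 0.7, atol=1e-6)
        assert np.allclose(s[30:], -0.3, atol=1e-6)

    def test_scores_sum_to_zero(self, null_cohort):
        covs = null_cohort.table[["age", "bmi"]]
        s = g.score_residuals(null_cohort.outcome, covs)
        assert abs(s.sum()) < 1e-6

    def test_strong_covariate_shrinks_case_scores(self):
        rng = np.random.default_rng(1)
        n = 5000
        z = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + 2.0 * z))))
        s = g.score_residuals(y, pd.DataFrame({"z": z}))
        s0 = g.score_residuals(y)
        # cases well-predicted by the covariate have smaller residuals
        assert s[y == 1].mean() < s0[y == 1].mean()


class TestLabelCells:
    def test_sum_rule(self):
        G = np.array([[0.0], [0.0]])
        cells = g.label_cells(G, np.array([0.6, -0.4]))
        cell0 = next(c for c in cells if c.key == (0,))
        assert cell0.score_sum == pytest.approx(0.2)
        assert cell0.label == "high"

    def test_empty_cell_low_risk(self):
        G = np.array([[0.0]])
        cells = g.label_cells(G, np.array([1.0]))
        assert next(c for c in cells if c.key == (2,)).label == "low"

    def test_all_negative_cell_low_risk(self):
        G = np.array([[1.0], [1.0]])
        cells = g.label_cells(G, np.array([-0.3, -0.3]))
        assert next(c for c in cells if c.key == (1,)).label == "low"

    def test_empty_input(self):
        assert g.label_cells(np.empty((0, 2)), np.array([])) == []


class TestBalancedAccuracy:
    def test_closed_form(self):
        # TP=8, FN=2, TN=6, FP=4 -> (0.8 + 0.6) / 2 = 0.7
        y = np.r_[np.ones(10), np.zeros(10)]
        pred = np.r_[np.ones(8), np.zeros(2), np.ones(4), np.zeros(6)]
        assert g.balanced_accuracy(pred, y) == pytest.approx(0.7)

    def test_perfect_separation(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        assert g.balanced_accuracy(y, y) == 1.0

    def test_degenerate_all_high_is_half(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        assert g.balanced_accuracy(np.ones(10), y) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            g.balanced_accuracy(np.ones(5), np.ones(5))


class TestCVPlan:
    def test_stratified_fold_sizes(self):
        rng = np.random.default_rng(2)
        y = rng.binomial(1, 0.05, 2000)
        plan = g.make_cv_plan(y, n_folds=10, seed=1)
        for cls in (0, 1):
            sizes = np.bincount(plan.folds[y == cls], minlength=10)
            assert sizes.max() - sizes.min() <= 1


class TestCrossValidate:
    def test_deterministic(self, planted_pair_cohort):
        ds = planted_pair_cohort
        y = ds.outcome
        s = g.score_residuals(y)
        plan = g.make_cv_plan(y, seed=5)
        G = ds.genotypes.dosages[:, :2]
        a = g.cross_validate(G, y, s, plan)
        b = g.cross_validate(G, y, s, plan)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_pair_teba_above_chance(self, planted_pair_cohort):
        ds = planted_pair_cohort
        y = ds.outcome
        s = g.score_residuals(y)
        plan = g.make_cv_plan(y, seed=5)
        cols = [ds.genotypes.snp_ids.index(s_) for s_ in ds.truth.planted_pairs[0]]
        cv = g.cross_validate(ds.genotypes.dosages[:, cols], y, s, plan)
        assert cv["teba"].mean() > 0.55

    def test_null_teba_centred_at_half(self):
        """Mean TEBA over 100 null datasets stays within 0.02 of 0.5."""
        means = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            n = 500
            G = rng.binomial(2, 0.3, (n, 2)).astype(float)
            y = rng.binomial(1, 0.3, n)
            if y.sum() in (0, n):
                continue
            s = g.score_residuals(y)
            plan = g.make_cv_plan(y, seed=rep)
            means.append(g.cross_validate(G, y, s, plan)["teba"].mean())
        assert abs(np.mean(means) - 0.5) < 0.02

    def test_training_optimism(self):
        """TRBA >= TEBA on average across simulated datasets."""
        diffs = []
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            n = 400
            G = rng.binomial(2, 0.3, (n, 2)).astype(float)
            y = rng.binomial(1, 0.3, n)
            if y.sum() in (0, n):
                continue
            s = g.score_residuals(y)
            cv = g.cross_validate(G, y, s, g.make_cv_plan(y, seed=rep))
            diffs.append(cv["trba"].mean() - cv["teba"].mean())
        assert np.mean(diffs) >= 0


class TestSignedRank:
    def test_extreme_all_above_null(self):
        vals = 0.5 + np.arange(1, 11) / 100
        assert g.signed_rank_test(vals) == pytest.approx(2 / 2 ** 10)

    def test_symmetric_values_near_one(self):
        vals = 0.5 + np.array([.01, -.01, .02, -.02, .03, -.03, .04, -.04, .05, -.05])
        assert g.signed_rank_test(vals) > 0.9

    def test_matches_scipy_exact_on_tie_free_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = 0.5 + rng.normal(0, 0.05, 10)
            expected = stats.wilcoxon(v - 0.5, method="exact").pvalue
            assert g.signed_rank_test(v) == pytest.approx(expected, abs=1e-12)

    def test_all_at_null_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert g.signed_rank_test(np.full(10, 0.5)) == 1.0

    def test_handles_ties_exactly(self):
        # duplicated magnitudes: midrank enumeration stays a valid p
        v = 0.5 + np.array([.02, .02, -.02, .03, .03, .01, -.01, .04, .04, .05])
        p = g.signed_rank_test(v)
        assert 0.0 < p <= 1.0


class TestSearch:
    def test_combination_count(self, planted_pair_cohort):
        ds = planted_pair_cohort
        total = sum(math.comb(10, k) for k in range(2, 9))
        assert total == 1002
        res = g.gmdr_search(ds.genotypes, ds.outcome, k_range=range(2, 9),
                            budget=1100, seed=1)
        assert res.n_evaluated == total

    def test_budget_guard(self, planted_pair_cohort):
        ds = planted_pair_cohort
        with pytest.raises(BudgetExceededError):
            g.gmdr_search(ds.genotypes, ds.outcome, k_range=range(2, 9), budget=100)

    def test_planted_pair_wins_with_full_consistency(self, planted_pair_cohort):
        ds = planted_pair_cohort
        plan = g.make_cv_plan(ds.outcome, seed=11)
        res = g.gmdr_search(ds.genotypes, ds.outcome, k_range=(2,), plan=plan)
        assert tuple(sorted(res.best.snp_ids)) == tuple(sorted(ds.truth.planted_pairs[0]))
        assert res.best.cvc == 10

    def test_enumeration_order_invariance(self, planted_pair_cohort):
        ds = planted_pair_cohort
        plan = g.make_cv_plan(ds.outcome, seed=11)
        fwd = g.gmdr_search(ds.genotypes, ds.outcome, candidates=ds.genotypes.snp_ids,
                            k_range=(2,), plan=plan)
        rev = g.gmdr_search(ds.genotypes, ds.outcome,
                            candidates=list(reversed(ds.genotypes.snp_ids)),
                            k_range=(2,), plan=plan)
        assert sorted(fwd.best.snp_ids) == sorted(rev.best.snp_ids)
        assert fwd.best.cvc == rev.best.cvc

    def test_sample_order_invariance_given_plan(self, planted_pair_cohort):
        ds = planted_pair_cohort
        y = ds.outcome
        plan = g.make_cv_plan(y, seed=11)
        base = g.gmdr_search(ds.genotypes, y, k_range=(2,), plan=plan)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        gm_p = ds.genotypes.subset(sample_idx=perm)
        plan_p = g.CVPlan(folds=plan.folds[perm], n_folds=plan.n_folds, seed=plan.seed)
        permuted = g.gmdr_search(gm_p, y[perm], k_range=(2,), plan=plan_p)
        assert sorted(base.best.snp_ids) == sorted(permuted.best.snp_ids)
        assert base.best.cvc == permuted.best.cvc
        assert base.best.teba == pytest.approx(permuted.best.teba)

    def test_k1_labels_match_case_fraction_sign(self):
        """With intercept-only residuals, a single-SNP cell is high-risk
        iff its case fraction exceeds the cohort case fraction."""
        rng = np.random.default_rng(12)
        n = 2000
        G = rng.binomial(2, 0.3, (n, 1)).astype(float)
        y = rng.binomial(1, np.where(G[:, 0] == 2, 0.5, 0.3))
        s = g.score_residuals(y)
        cells = g.label_cells(G, s)
        pbar = y.mean()
        for c in cells:
            if c.n == 0:
                continue
            frac = y[G[:, 0] == c.key[0]].mean()
            if abs(frac - pbar) > 1e-12:
                assert (c.label == "high") == (frac > pbar)
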