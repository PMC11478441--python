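"""Genotype QC: HWE exact test vs enumeration oracle, SNP stats, filtering,
EM D-prime, and LD pruning."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gmdrprs as g
from gmdrprs.datatypes import default_snp_meta
from gmdrprs.errors import ParameterError, UndefinedStatisticError
from gmdrprs.qc import QCThresholds


def _gm(columns: dict, meta=None):
    ids = list(columns)
    d = np.column_stack([np.asarray(columns[s], dtype=float) for s in ids])
    samples = [f"S{i}" for i in range(d.shape[0])]
    return g.GenotypeMatrix(d, ids, samples, meta if meta is not None else default_snp_meta(ids))


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert g.hwe_exact_test(100, 0, 0) == 1.0

    def test_extreme_heterozygote_excess(self):
        assert g.hwe_exact_test(0, 100, 0) < 1e-10

    def test_equals_enumeration_oracle_exhaustively(self, hwe_oracle):
        """Recurrence-based p equals direct multinomial enumeration for
        every genotype table with total count <= 50."""
        for n in range(1, 51):
            for n_aa in range(n + 1):
                for n_het in range(n - n_aa + 1):
                    n_AA = n - n_aa - n_het
                    p = g.hwe_exact_test(n_AA, n_het, n_aa)
                    assert p == pytest.approx(hwe_oracle(n_AA, n_het, n_aa), rel=1e-9)
                    assert 0.0 < p <= 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            g.hwe_exact_test(0, 0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            g.hwe_exact_test(-1, 2, 3)


class TestSNPStats:
    def test_hand_counted_column(self):
        stats = g.compute_snp_stats(_gm({"x": [0, 0, 1, 1]}))
        row = stats.loc["x"]
        assert row["maf"] == pytest.approx(0.25)
        assert row["het_rate"] == pytest.approx(0.5)
        assert row["call_rate"] == pytest.approx(1.0)

    def test_all_missing_flagged(self):
        stats = g.compute_snp_stats(_gm({"x": [np.nan] * 4}))
        assert bool(stats.loc["x", "flagged"]) and stats.loc["x", "call_rate"] == 0

    def test_frequency_folding_swaps_alleles(self):
        stats = g.compute_snp_stats(_gm({"x": [2, 2, 2, 2]}))
        assert stats.loc["x", "maf"] == 0.0
        # coded allele was the common one, so labels swap
        assert stats.loc["x", "minor_allele"] == "G"
        assert stats.loc["x", "major_allele"] == "A"


class TestApplyQC:
    def test_rare_snp_removed_for_maf(self):
        rng = np.random.default_rng(0)
        rare = rng.binomial(2, 0.005, 2000)
        common = rng.binomial(2, 0.3, 2000)
        gm = _gm({"rare": rare, "common": common})
        kept, report = g.apply_qc(gm)
        assert "maf" in report.table.loc["rare", "fail_reasons"]
        assert "rare" not in kept.snp_ids

    def test_common_high_het_snp_kept(self):
        # het fraction ~0.42 at MAF 0.3 must NOT exclude the SNP
        rng = np.random.default_rng(1)
        gm = _gm({"x": rng.binomial(2, 0.3, 5000)})
        kept, report = g.apply_qc(gm)
        assert report.table.loc["x", "het_rate"] > 0.35
        assert "x" in kept.snp_ids

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        cols = {f"ok{i}": rng.binomial(2, 0.3, 1000) for i in range(7)}
        cols.update({f"bad{i}": rng.binomial(2, 0.004, 1000) for i in range(3)})
        _, report = g.apply_qc(_gm(cols))
        assert report.n_kept + report.n_removed == report.n_input == 10
        assert report.n_removed >= 3

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        cols = {f"s{i}": rng.binomial(2, 0.2, 800) for i in range(5)}
        gm = _gm(cols)
        once, r1 = g.apply_qc(gm)
        twice, r2 = g.apply_qc(once)
        assert once.snp_ids == twice.snp_ids
        assert r2.n_removed == 0 or r2.n_kept == r1.n_kept

    def test_empty_result_warns_not_raises(self):
        gm = _gm({"x": [0, 0, 0, 0]})  # monomorphic -> maf fail
        with pytest.warns(UserWarning):
            kept, report = g.apply_qc(gm)
        assert kept.n_snps == 0 and report.n_kept == 0

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            QCThresholds(min_maf=1.5)


class TestDprime:
    def test_duplicated_column_is_one(self):
        rng = np.random.default_rng(4)
        x = rng.binomial(2, 0.3, 2000).astype(float)
        assert g.estimate_dprime(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.binomial(2, 0.3, 3000).astype(float)
        b = rng.binomial(2, 0.2, 3000).astype(float)
        assert g.estimate_dprime(a, b) == pytest.approx(g.estimate_dprime(b, a))

    def test_closed_form_on_known_phase(self):
        """Genotypes built from an exact haplotype-pair table recover the
        closed-form D' of the true haplotype frequencies."""
        # haplotype freqs for (a,b), (a,B), (A,b), (A,B)
        f = {(1, 1): 0.14, (1, 0): 0.06, (0, 1): 0.26, (0, 0): 0.54}
        p_a, p_b = 0.20, 0.40
        d = f[(1, 1)] - p_a * p_b                      # 0.06
        d_true = d / min(p_a * (1 - p_b), (1 - p_a) * p_b)  # 0.5
        g1, g2 = [], []
        for h1, c1 in f.items():
            for h2, c2 in f.items():
                n_pair = round(c1 * c2 * 10_000)       # exact integers
                g1.extend([h1[0] + h2[0]] * n_pair)
                g2.extend([h1[1] + h2[1]] * n_pair)
        est = g.estimate_dprime(np.array(g1, float), np.array(g2, float))
        assert est == pytest.approx(d_true, abs=1e-6)

    def test_monomorphic_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            g.estimate_dprime(np.zeros(100), np.ones(100))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10 ** 6))
    def test_range_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.binomial(2, rng.uniform(0.05, 0.5), 300).astype(float)
        b = rng.binomial(2, rng.uniform(0.05, 0.5), 300).astype(float)
        if a.std() == 0 or b.std() == 0:
            return
        assert 0.0 <= g.estimate_dprime(a, b) <= 1.0

    def test_hwe_type_one_error_calibrated(self):
        """Under HWE at n=2000, the 5% exact test rejects <= 7% of SNPs."""
        specs = [g.SNPSpec(id=f"s{i}", maf=0.05 + 0.0015 * i) for i in range(300)]
        gm = g.simulate_genotypes(specs, 2000, seed=13)
        stats = g.compute_snp_stats(gm)
        assert (stats["hwe_p"] <= 0.05).mean() <= 0.07


class TestLDPrune:
    def _dp(self, vals):
        ids = sorted({i for pair in vals for i in pair})
        m = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        for (a, b), v in vals.items():
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def test_keeps_smaller_p_of_linked_pair(self):
        dp = self._dp({("a", "b"): 0.9})
        kept = g.ld_prune(["a", "b"], dp, {"a": 1e-6, "b": 1e-3}, threshold=0.4)
        assert kept == ["a"]

    def test_unlinked_all_kept(self):
        dp = self._dp({("a", "b"): 0.0, ("a", "c"): 0.0, ("b", "c"): 0.0})
        assert g.ld_prune(["a", "b", "c"], dp, {"a": .1, "b": .2, "c": .3}) == ["a", "b", "c"]

    def test_missing_p_rejected(self):
        dp = self._dp({("a", "b"): 0.9})
        with pytest.raises(ParameterError):
            g.ld_prune(["a", "b"], dp, {"a": 1e-6}, threshold=0.4)

    def test_clustered_ld_postcondition(self):
        """Pruning a panel with LD clusters leaves no retained pair at or
        above the threshold."""
        specs = []
        for c in range(6):
            specs.append(g.SNPSpec(id=f"c{c}_anchor", maf=0.3))
            for k in range(2):
                specs.append(g.SNPSpec(id=f"c{c}_tag{k}", maf=0.25,
                                       ld_partner=f"c{c}_anchor", ld_dprime=0.9))
        gm = g.simulate_genotypes(specs, 4000, seed=17)
        ids = gm.snp_ids
        dp = g.dprime_matrix(gm, ids)
        rng = np.random.default_rng(0)
        pvals = {s: rng.uniform(1e-6, 1e-3) for s in ids}
        kept = g.ld_prune(ids, dp, pvals, threshold=0.4)
        assert len(kept) < len(ids)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert dp.loc[a, b] < 0.4
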