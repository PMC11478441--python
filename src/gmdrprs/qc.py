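"""SNP-level quality control and linkage-disequilibrium pruning.

QC thresholds follow the conventional chip-QC recipe: per-SNP call rate
(missing rate < 4%), minor allele frequency (MAF > 0.01), heterozygosity
(< 30%) and Hardy-Weinberg equilibrium (exact-test p > 0.05).  LD between
unphased SNP pairs is summarised by D' (|D| / D_max), estimated with an EM
resolution of the double-heterozygote phase ambiguity, and strongly linked
pairs (D' >= 0.4 by default) are greedily pruned keeping the SNP with the
smaller association p-value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .errors import ParameterError, UndefinedStatisticError

__all__ = [
    "QCThresholds", "QCReport", "hwe_exact_test", "compute_snp_stats",
    "apply_qc", "estimate_dprime", "dprime_matrix", "ld_prune",
]


@dataclass
class QCThresholds:
    """QC thresholds (all fractions/probabilities in [0, 1]).

    ``max_missing``, ``min_maf`` and ``min_hwe_p`` exclude SNPs.
    ``max_het`` is the per-sample heterozygosity ceiling: under HWE a
    common SNP routinely has 40-50% heterozygotes, so a 30% cap is only
    meaningful across a sample's genotypes (excess sample heterozygosity
    signals contamination), not per SNP.  High-het samples are listed in
    the report; they are dropped only when ``apply_qc`` is called with
    ``filter_samples=True``.
    """

    max_missing: float = 0.04
    min_maf: float = 0.01
    min_hwe_p: float = 0.05
    max_het: float = 0.30

    def __post_init__(self):
        for name in ("max_missing", "min_maf", "min_hwe_p", "max_het"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Outcome of :func:`apply_qc`: per-SNP verdicts plus summary counts."""

    table: pd.DataFrame           # per-SNP stats, pass flag, failure reasons
    n_input: int
    n_kept: int
    n_removed: int
    sample_het: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    thresholds: QCThresholds = field(default_factory=QCThresholds)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows a known discrete distribution; the p-value sums the
    probabilities of all heterozygote counts no more likely than the one
    observed (the standard exact-test convention).  Computed with the usual
    stable recurrence over heterozygote counts of matching parity.

    Returns 1.0 for a monomorphic SNP; raises for an all-zero table.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ParameterError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined for an all-zero genotype table")
    # rare-allele count; relabel so 'a' is the rarer allele
    n_a = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_a == 0:
        return 1.0

    # probabilities over all heterozygote counts with the parity of n_a,
    # anchored at the distribution's mode for numerical stability
    het_min = n_a % 2
    hets = list(range(het_min, n_a + 1, 2))
    probs = np.zeros(len(hets))
    mode = int(round(n_a * (2 * n - n_a) / (2.0 * n)))
    if (mode - het_min) % 2 != 0:
        mode += 1 if mode < n_a else -1
    mid = hets.index(mode)
    probs[mid] = 1.0
    # downward: P(h-2)/P(h) = h(h-1) / (4 (n_rr+1)(n_cc+1))
    for i in range(mid, 0, -1):
        h = hets[i]
        n_rr = (n_a - h) // 2          # rare homozygotes at het count h
        n_cc = n - h - n_rr            # common homozygotes
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (n_rr + 1) * (n_cc + 1))
    # upward: P(h+2)/P(h) = 4 n_rr n_cc / ((h+2)(h+1))
    for i in range(mid, len(hets) - 1):
        h = hets[i]
        n_rr = (n_a - h) // 2
        n_cc = n - h - n_rr
        probs[i + 1] = probs[i] * 4.0 * n_rr * n_cc / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()

    obs_idx = hets.index(n_Aa) if n_Aa in hets else None
    if obs_idx is None:  # pragma: no cover - parity always matches by construction
        raise ParameterError("observed heterozygote count inconsistent with allele count")
    p_obs = probs[obs_idx]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


_MISSING_STATS = {"maf": np.nan, "call_rate": 0.0, "het_rate": np.nan, "hwe_p": np.nan}


def _sample_het(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-sample heterozygote fraction over that sample's called genotypes."""
    called = (~np.isnan(genotypes.dosages)).sum(axis=1)
    return (genotypes.dosages == 1).sum(axis=1) / np.maximum(called, 1)


def compute_snp_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP MAF, call rate, heterozygote fraction and HWE exact p.

    Allele frequencies are folded onto the minor allele: when the coded
    allele's frequency exceeds 0.5 among non-missing calls, the reported
    MAF is ``1 - freq`` and the minor/major labels are swapped in the
    output.  A SNP with zero non-missing calls is flagged and its
    statistics set to missing sentinels (call_rate 0, others NaN).
    """
    if genotypes.n_samples < 1:
        raise ParameterError("need at least one sample")
    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        col = genotypes.dosages[:, j]
        meta = genotypes.snps.loc[snp]
        called = col[~np.isnan(col)]
        n = genotypes.n_samples
        if called.size == 0:
            rows.append({"id": snp, "chrom": meta["chrom"], "pos": meta["pos"],
                         "minor_allele": meta["minor_allele"],
                         "major_allele": meta["major_allele"],
                         **_MISSING_STATS, "n_called": 0, "flagged": True})
            continue
        counts = np.bincount(called.astype(int), minlength=3)
        freq = called.mean() / 2.0
        minor, major = meta["minor_allele"], meta["major_allele"]
        maf = freq
        if freq > 0.5:
            maf = 1.0 - freq
            minor, major = major, minor
        rows.append({
            "id": snp, "chrom": meta["chrom"], "pos": meta["pos"],
            "minor_allele": minor, "major_allele": major,
            "maf": float(maf),
            "call_rate": called.size / n,
            "het_rate": counts[1] / called.size,
            "hwe_p": hwe_exact_test(counts[2], counts[1], counts[0]),
            "n_called": int(called.size),
            "flagged": False,
        })
    return pd.DataFrame(rows).set_index("id")


def apply_qc(genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None,
             filter_samples: bool = False) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs (and optionally samples) against the QC thresholds.

    A SNP is kept iff call_rate >= 1 - max_missing, MAF > min_maf and
    HWE p > min_hwe_p; the report lists every failing criterion.  Sample
    heterozygosity is always reported; samples at or above ``max_het`` are
    excluded only when ``filter_samples`` is set (sample QC is normally a
    separate upstream step).  Idempotent.
    """
    thresholds = thresholds or QCThresholds()
    if filter_samples:
        het = _sample_het(genotypes)
        keep = np.flatnonzero(het < thresholds.max_het)
        genotypes = genotypes.subset(sample_idx=keep)
    stats = compute_snp_stats(genotypes)

    reasons = []
    for snp, row in stats.iterrows():
        r = []
        if row["flagged"] or row["call_rate"] < 1.0 - thresholds.max_missing:
            r.append("call_rate")
        if not (row["maf"] > thresholds.min_maf):
            r.append("maf")
        if not (row["hwe_p"] > thresholds.min_hwe_p):
            r.append("hwe")
        reasons.append(",".join(r))
    stats = stats.copy()
    stats["fail_reasons"] = reasons
    stats["pass"] = stats["fail_reasons"] == ""

    kept_ids = list(stats.index[stats["pass"]])
    report = QCReport(
        table=stats,
        n_input=genotypes.n_snps,
        n_kept=len(kept_ids),
        n_removed=genotypes.n_snps - len(kept_ids),
        sample_het=pd.Series(_sample_het(genotypes), index=genotypes.sample_ids,
                             name="sample_het"),
        thresholds=thresholds,
    )
    if not kept_ids:
        warnings.warn("QC removed every SNP", UserWarning, stacklevel=2)
        filtered = genotypes.subset(snp_ids=[])
    else:
        filtered = genotypes.subset(snp_ids=kept_ids)
    return filtered, report


def _em_haplotype_freqs(counts: np.ndarray, tol: float = 1e-8,
                        max_iter: int = 1000) -> np.ndarray:
    """EM estimate of the four haplotype frequencies (f11, f10, f01, f00)
    from a 3x3 table of unphased two-locus genotype counts (index =
    minor-allele dosage).  Only the double heterozygote is phase-ambiguous."""
    n = counts.sum()
    # fixed haplotype contributions from phase-unambiguous cells;
    # order: ab(11), aB(10), Ab(01), AB(00) with a/b the coded alleles
    base = np.zeros(4)
    idx = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            if i in (0, 2) and j in (0, 2):        # both homozygous: phase known
                base[idx[(i // 2, j // 2)]] += 2 * c
            elif i == 1:                           # a heterozygous, b homozygous
                base[idx[(1, j // 2)]] += c
                base[idx[(0, j // 2)]] += c
            else:                                  # b heterozygous, a homozygous
                base[idx[(i // 2, 1)]] += c
                base[idx[(i // 2, 0)]] += c
    dh = counts[1, 1]
    f = np.full(4, 0.25)
    for _ in range(max_iter):
        if dh > 0:
            num_cis = f[0] * f[3]                  # ab/AB resolution
            num_trans = f[1] * f[2]                # aB/Ab resolution
            w = 0.5 if num_cis + num_trans == 0 else num_cis / (num_cis + num_trans)
        else:
            w = 0.0
        hap = base.copy()
        hap[0] += dh * w
        hap[3] += dh * w
        hap[1] += dh * (1 - w)
        hap[2] += dh * (1 - w)
        new = hap / (2.0 * n)
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def estimate_dprime(g1: np.ndarray, g2: np.ndarray) -> float:
    """Normalised LD coefficient D' between two unphased dosage vectors.

    Haplotype frequencies are estimated by EM over complete sample pairs
    (double-heterozygote ambiguity resolved iteratively to 1e-8), then
    D' = |D| / D_max where D = f_ab - p_a p_b.  Symmetric in its arguments;
    raises for a pair leaving either SNP monomorphic.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    a, b = g1[ok].astype(int), g2[ok].astype(int)
    if a.size == 0:
        raise UndefinedStatisticError("no complete genotype pairs")
    counts = np.zeros((3, 3))
    np.add.at(counts, (a, b), 1)
    p_a = a.mean() / 2.0
    p_b = b.mean() / 2.0
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedStatisticError("D' undefined for a monomorphic SNP")
    f = _em_haplotype_freqs(counts)
    d = f[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max <= 0:  # pragma: no cover - excluded by the polymorphism check
        raise UndefinedStatisticError("degenerate allele frequencies")
    return float(min(1.0, abs(d) / d_max))


def dprime_matrix(genotypes: GenotypeMatrix, snp_ids=None) -> pd.DataFrame:
    """Symmetric matrix of pairwise D' values (diagonal = 1)."""
    ids = list(snp_ids) if snp_ids is not None else genotypes.snp_ids
    m = len(ids)
    out = np.eye(m)
    cols = {s: genotypes.column(s) for s in ids}
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = estimate_dprime(cols[ids[i]], cols[ids[j]])
    return pd.DataFrame(out, index=ids, columns=ids)


def ld_prune(snp_ids, dprime: pd.DataFrame, gwas_p, threshold: float = 0.4,
             positions=None) -> list[str]:
    """Greedy pruning of strongly linked SNP pairs.

    While any retained pair has D' >= ``threshold``, the member with the
    larger association p-value is dropped (ties broken by genomic order:
    the later SNP is dropped).  The result's pairwise D' are all below the
    threshold; input order is preserved.
    """
    ids = list(snp_ids)
    gwas_p = dict(gwas_p)
    missing = [s for s in ids if s not in gwas_p or pd.isna(gwas_p[s])]
    if missing:
        raise ParameterError(f"missing GWAS p-value for: {', '.join(missing)}")
    order = {s: (positions[s] if positions is not None else i)
             for i, s in enumerate(ids)}
    kept = list(ids)
    while True:
        worst = None
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                a, b = kept[i], kept[j]
                d = dprime.loc[a, b]
                if d >= threshold and (worst is None or d > worst[0]):
                    worst = (d, a, b)
        if worst is None:
            return kept
        _, a, b = worst
        if gwas_p[a] > gwas_p[b]:
            drop = a
        elif gwas_p[b] > gwas_p[a]:
            drop = b
        else:
            drop = a if order[a] > order[b] else b
        kept.remove(drop)
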