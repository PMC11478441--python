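"""Generalized multifactor dimensionality reduction (GMDR) engine.

GMDR screens SNP combinations for joint (epistatic) effects on a binary
outcome.  Each sample carries a score residual s_i = y_i - p_hat_i from a
null (covariates-only) logistic model; every multilocus genotype cell is
labelled high-risk when its summed residuals exceed a threshold (0 by
convention, since residuals are centred).  A combination's quality is the
balanced accuracy of the induced high/low classification, evaluated by
stratified 10-fold cross-validation: trained balanced accuracy (TRBA) on
the 9/10 training part, testing balanced accuracy (TEBA) on the held-out
1/10.  Cross-validation consistency (CVC) counts the folds in which a
combination is the fold-best model; significance of a model's fold TEBAs
against the null value 0.5 uses an exact Wilcoxon signed-rank test.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import build_design, fit_logistic
from .datatypes import GenotypeMatrix
from .errors import (BudgetExceededError, ConvergenceError, ParameterError,
                     UndefinedStatisticError)

__all__ = [
    "CVPlan", "GenotypeCell", "GMDRModel", "GMDRSearchResult",
    "score_residuals", "make_cv_plan", "label_cells", "balanced_accuracy",
    "cross_validate", "signed_rank_test", "gmdr_search",
]


@dataclass
class CVPlan:
    """Fold assignment (0..n_folds-1 per sample), stratified by case status."""

    folds: np.ndarray
    n_folds: int
    seed: int


@dataclass
class GenotypeCell:
    """One multilocus genotype cell with its pooled score evidence."""

    key: tuple
    n: int
    score_sum: float
    label: str  # "high" | "low"


@dataclass
class GMDRModel:
    """One evaluated SNP combination with its CV summary statistics."""

    snp_ids: tuple
    trba: float
    teba: float
    cvc: int
    n_folds: int
    signed_rank_p: float            # fold TEBAs vs 0.5
    signed_rank_p_trba: float       # fold TRBAs vs 0.5 (reported alongside)
    trba_folds: np.ndarray = field(repr=False, default=None)
    teba_folds: np.ndarray = field(repr=False, default=None)


@dataclass
class GMDRSearchResult:
    best_per_k: dict[int, GMDRModel]
    best: GMDRModel
    n_evaluated: int


def score_residuals(outcome, covariates: pd.DataFrame | None = None) -> np.ndarray:
    """Score residuals s_i = y_i - p_hat_i from the covariates-only model.

    With no covariates this reduces to y_i minus the case fraction, so the
    residuals always sum to ~0 (score equation of the intercept).
    """
    y = np.asarray(outcome, dtype=float)
    X = build_design(covariates) if covariates is not None else pd.DataFrame(
        {"const": np.ones(len(y))})
    X.index = range(len(y))
    fit = fit_logistic(y, X)
    if not fit.converged:
        raise ConvergenceError("null (covariates-only) model did not converge")
    eta = X.to_numpy() @ fit.params.to_numpy()
    p_hat = 1.0 / (1.0 + np.exp(-eta))
    return y - p_hat


def make_cv_plan(outcome, n_folds: int = 10, seed: int = 0) -> CVPlan:
    """Stratified fold assignment: within each outcome class, a seeded
    permutation is dealt round-robin, so class fold sizes differ by <= 1."""
    y = np.asarray(outcome)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % n_folds
    return CVPlan(folds=folds, n_folds=n_folds, seed=seed)


def _codes(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """(complete-row mask, integer cell code per complete row, n_cells)."""
    complete = ~np.isnan(G).any(axis=1)
    k = G.shape[1]
    powers = 3 ** np.arange(k)
    codes = (G[complete].astype(int) * powers).sum(axis=1)
    return complete, codes, 3 ** k


def label_cells(G: np.ndarray, scores: np.ndarray, threshold: float = 0.0
                ) -> list[GenotypeCell]:
    """Pool samples into multilocus cells and label each high/low risk.

    A cell is high-risk iff its summed score residuals exceed ``threshold``
    (strictly); empty cells are low-risk by default.  Samples with a
    missing genotype at any of the combination's SNPs are excluded.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.ndim != 2:
        raise ParameterError("G must be (n_samples, k)")
    if G.shape[0] == 0:
        return []
    complete, codes, n_cells = _codes(G)
    s = np.asarray(scores, dtype=float)[complete]
    sums = np.bincount(codes, weights=s, minlength=n_cells)
    counts = np.bincount(codes, minlength=n_cells)
    k = G.shape[1]
    cells = []
    for c in range(n_cells):
        key = tuple((c // 3 ** i) % 3 for i in range(k))
        label = "high" if sums[c] > threshold else "low"
        cells.append(GenotypeCell(key=key, n=int(counts[c]),
                                  score_sum=float(sums[c]), label=label))
    return cells


def balanced_accuracy(pred_high: np.ndarray, outcome: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 of the high-risk prediction."""
    y = np.asarray(outcome).astype(bool)
    pred = np.asarray(pred_high).astype(bool)
    if y.all() or (~y).all():
        raise UndefinedStatisticError(
            "balanced accuracy undefined on a single-class evaluation set")
    sens = pred[y].mean()
    spec = (~pred[~y]).mean()
    return float((sens + spec) / 2.0)


def cross_validate(G: np.ndarray, outcome, scores, plan: CVPlan,
                   threshold: float = 0.0) -> pd.DataFrame:
    """Per-fold TRBA/TEBA for one SNP combination.

    Cells are labelled on each 9/10 training part; held-out samples whose
    cell was empty (or unseen) in training are predicted low-risk.  Folds
    whose training or test part is single-class are recorded as skipped
    (NaN accuracies).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    y = np.asarray(outcome, dtype=int)
    s = np.asarray(scores, dtype=float)
    complete, codes_all, n_cells = _codes(G)
    idx_complete = np.flatnonzero(complete)
    folds = plan.folds[idx_complete]
    y_c, s_c = y[idx_complete], s[idx_complete]

    rows = []
    for f in range(plan.n_folds):
        train = folds != f
        test = ~train
        rec = {"fold": f, "trba": np.nan, "teba": np.nan, "skipped": False}
        if len(set(y_c[train])) < 2 or len(set(y_c[test])) < 2:
            rec["skipped"] = True
            rows.append(rec)
            continue
        sums = np.bincount(codes_all[train], weights=s_c[train], minlength=n_cells)
        high = sums > threshold
        rec["trba"] = balanced_accuracy(high[codes_all[train]], y_c[train])
        rec["teba"] = balanced_accuracy(high[codes_all[test]], y_c[test])
        rows.append(rec)
    return pd.DataFrame(rows).set_index("fold")


def signed_rank_test(values, null_value: float = 0.5) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value against ``null_value``.

    Differences of exactly zero are dropped (with a warning); ties among
    the non-zero magnitudes get midranks.  For up to 20 informative values
    the full 2^n sign-pattern distribution is enumerated (exact even with
    ties); beyond that the normal approximation is used.
    """
    d = np.asarray(values, dtype=float) - null_value
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        warnings.warn("all values equal the null; signed-rank p = 1", UserWarning,
                      stacklevel=2)
        return 1.0
    if n <= 20:
        r = stats.rankdata(np.abs(nz))
        w_obs = r[nz > 0].sum()
        patterns = np.arange(2 ** n, dtype=np.uint32)
        bits = (patterns[:, None] >> np.arange(n)) & 1
        w_all = bits @ r
        tol = 1e-9
        p_lo = np.mean(w_all <= w_obs + tol)
        p_hi = np.mean(w_all >= w_obs - tol)
        return float(min(1.0, 2.0 * min(p_lo, p_hi)))
    res = stats.wilcoxon(nz, alternative="two-sided", correction=True,
                         method="approx")
    return float(res.pvalue)


def _combo_sort_key(ids: tuple) -> tuple:
    return tuple(sorted(ids))


def gmdr_search(genotypes: GenotypeMatrix, outcome, covariates: pd.DataFrame | None = None,
                candidates: list[str] | None = None, k_range=(1, 2),
                plan: CVPlan | None = None, threshold: float = 0.0,
                budget: int = 20000, n_folds: int = 10, seed: int = 0
                ) -> GMDRSearchResult:
    """Exhaustive cross-validated search over k-SNP combinations.

    For every k in ``k_range`` all k-combinations of the candidate SNPs are
    cross-validated.  In each fold the combination with the highest TRBA is
    the fold-best (ties: lexicographically smallest SNP-id tuple, making
    the result independent of enumeration order); the per-k best model is
    the modal fold-best (CVC = its fold count; ties broken by higher mean
    TEBA, then lexicographic ids).  The overall best is the per-k model
    with the smallest TEBA signed-rank p (ties: higher CVC, then higher
    TEBA).

    Raises :class:`BudgetExceededError` before evaluating anything if the
    total combination count exceeds ``budget``.
    """
    candidates = list(candidates) if candidates is not None else list(genotypes.snp_ids)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1 or ks[-1] > len(candidates):
        raise ParameterError(f"k_range must lie within [1, {len(candidates)}]")
    total = sum(math.comb(len(candidates), k) for k in ks)
    if total > budget:
        raise BudgetExceededError(
            f"{total} combinations exceed the budget of {budget}; "
            "narrow k_range or the candidate list")

    y = np.asarray(outcome, dtype=int)
    scores = score_residuals(y, covariates)
    plan = plan or make_cv_plan(y, n_folds=n_folds, seed=seed)

    col_idx = {s: genotypes.snp_ids.index(s) for s in candidates}
    D = genotypes.dosages

    best_per_k: dict[int, GMDRModel] = {}
    n_eval = 0
    for k in ks:
        fold_best = [None] * plan.n_folds   # (trba, sort_key, ids, teba_folds, trba_folds)
        combo_stats = {}
        for ids in itertools.combinations(candidates, k):
            G = D[:, [col_idx[s] for s in ids]]
            cv = cross_validate(G, y, scores, plan, threshold)
            n_eval += 1
            combo_stats[ids] = cv
            key = _combo_sort_key(ids)
            for f in range(plan.n_folds):
                t = cv["trba"].iloc[f]
                if np.isnan(t):
                    continue
                cur = fold_best[f]
                if (cur is None or t > cur[0] + 1e-12
                        or (abs(t - cur[0]) <= 1e-12 and key < cur[1])):
                    fold_best[f] = (t, key, ids)
        # CVC tally over fold-best combinations
        tally: dict[tuple, int] = {}
        for fb in fold_best:
            if fb is not None:
                tally[fb[2]] = tally.get(fb[2], 0) + 1
        if not tally:
            continue

        def model_for(ids: tuple) -> GMDRModel:
            cv = combo_stats[ids]
            teba = cv["teba"].dropna().to_numpy()
            trba = cv["trba"].dropna().to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                p_teba = signed_rank_test(teba) if teba.size else 1.0
                p_trba = signed_rank_test(trba) if trba.size else 1.0
            return GMDRModel(snp_ids=ids, trba=float(np.mean(trba)),
                             teba=float(np.mean(teba)), cvc=tally.get(ids, 0),
                             n_folds=plan.n_folds, signed_rank_p=p_teba,
                             signed_rank_p_trba=p_trba,
                             trba_folds=cv["trba"].to_numpy(),
                             teba_folds=cv["teba"].to_numpy())

        def k_rank(ids: tuple):
            teba = combo_stats[ids]["teba"].mean()
            return (-tally[ids], -teba, _combo_sort_key(ids))

        best_ids = min(tally.keys(), key=k_rank)
        best_per_k[k] = model_for(best_ids)

    if not best_per_k:
        raise UndefinedStatisticError("no evaluable combination (all folds single-class)")
    best = min(best_per_k.values(),
               key=lambda m: (m.signed_rank_p, -m.cvc, -m.teba, _combo_sort_key(m.snp_ids)))
    return GMDRSearchResult(best_per_k=best_per_k, best=best, n_evaluated=n_eval)


def search_table(result: GMDRSearchResult) -> pd.DataFrame:
    """Model-selection table (one row per k) mirroring the usual GMDR report."""
    rows = []
    for k in sorted(result.best_per_k):
        m = result.best_per_k[k]
        rows.append({"k": k, "snp_ids": ",".join(m.snp_ids), "trba": m.trba,
                     "teba": m.teba, "cvc": f"{m.cvc}/{m.n_folds}",
                     "signed_rank_p": m.signed_rank_p,
                     "signed_rank_p_trba": m.signed_rank_p_trba,
                     "best": m is result.best})
    return pd.DataFrame(rows).set_index("k")
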