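"""Shared logistic-regression machinery and the covariate-adjusted GWAS scan.

Model fitting is maximum likelihood via Newton iterations (iteratively
reweighted least squares), delegated to ``statsmodels``; this module wraps
it with a stable fit container, Wald odds ratios with 95% confidence
intervals, likelihood-ratio tests, and a per-SNP additive-coding scan with
a liberal screening threshold (default alpha = 5e-4) suited to rare
outcomes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GenotypeMatrix
from .errors import ConvergenceError, ParameterError

__all__ = ["GLMFit", "ORResult", "fit_logistic", "wald_or", "lrt",
           "build_design", "gwas_scan", "COVARIATE_SETS"]

# Named covariate presets: the GWAS-screen adjustment set and the
# association/stratified-analysis adjustment set (the two differ slightly;
# both are exposed rather than guessing which applies where).
COVARIATE_SETS = {
    "covariate_set_1": ["age", "sex", "residence", "bmi", "energy_pct",
                        "education", "income"],
    "covariate_set_2": ["age", "sex", "bmi", "residence", "activity",
                        "education", "income", "smoking", "alcohol", "energy_pct"],
}

_MAX_ABS_COEF = 30.0  # |log-odds| beyond this is treated as separation


@dataclass
class GLMFit:
    """Converged-or-flagged logistic fit."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    nobs: int

    def __post_init__(self):
        if self.converged and self.loglik > 1e-9:
            raise ParameterError("log-likelihood of a Bernoulli model cannot be positive")


@dataclass
class ORResult:
    """Odds ratio with 95% Wald confidence interval and two-sided p."""

    or_point: float
    ci_low: float
    ci_high: float
    p: float
    reference_label: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ParameterError("CI must bracket the point estimate")


def fit_logistic(y, X: pd.DataFrame) -> GLMFit:
    """Fit outcome ~ X by Newton/IRLS to convergence (tol 1e-10, <=100 it).

    ``X`` is the full design matrix (include an intercept column).  Rows
    with any missing value in ``y`` or ``X`` must be removed by the caller.
    Quasi-complete separation is flagged as a non-converged fit rather than
    silently returned.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ParameterError("y must be binary 0/1")
    Xv = X.astype(float)
    if np.isnan(Xv.to_numpy()).any() or np.isnan(y).any():
        raise ParameterError("missing values in design; restrict to complete cases first")
    if Xv.shape[0] < Xv.shape[1]:
        raise ParameterError("fewer complete-case rows than design columns")
    if np.linalg.matrix_rank(Xv.to_numpy()) < Xv.shape[1]:
        raise ParameterError("design matrix is rank deficient")

    model = sm.Logit(y, Xv)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0,
                            warn_convergence=False)
        params = pd.Series(res.params, index=Xv.columns)
        bse = pd.Series(res.bse, index=Xv.columns)
        ok = (bool(res.mle_retvals.get("converged", False))
              and np.isfinite(params).all() and np.isfinite(bse).all()
              and params.abs().max() < _MAX_ABS_COEF)
        return GLMFit(params=params, bse=bse, loglik=float(res.llf),
                      converged=bool(ok),
                      n_iter=int(res.mle_retvals.get("iterations", -1)),
                      nobs=int(res.nobs))
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        nan = pd.Series(np.nan, index=Xv.columns)
        return GLMFit(params=nan, bse=nan.copy(), loglik=np.nan,
                      converged=False, n_iter=-1, nobs=int(len(y)))


def wald_or(fit: GLMFit, term: str, reference_label: str = "") -> ORResult:
    """Wald odds ratio for one design term: exp(beta +/- 1.96 SE)."""
    if not fit.converged:
        raise ConvergenceError(
            "cannot form a Wald OR from a non-converged fit",
            diagnostics={"n_iter": fit.n_iter, "params": fit.params.to_dict()})
    if term not in fit.params.index:
        raise ParameterError(f"term {term!r} not in fit")
    b, se = float(fit.params[term]), float(fit.bse[term])
    if not np.isfinite(se):
        raise ConvergenceError(f"non-finite standard error for {term!r}")
    z = b / se if se > 0 else np.inf * np.sign(b)
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return ORResult(or_point=float(np.exp(b)),
                    ci_low=float(np.exp(b - 1.96 * se)),
                    ci_high=float(np.exp(b + 1.96 * se)),
                    p=float(p), reference_label=reference_label)


def lrt(full: GLMFit, reduced: GLMFit, df: int) -> float:
    """Likelihood-ratio test p-value for nested logistic models."""
    if not (full.converged and reduced.converged):
        raise ConvergenceError("LRT requires two converged fits")
    delta = full.loglik - reduced.loglik
    if delta < -1e-8:
        raise ParameterError(
            f"reduced model fits better (delta ll = {delta:.3g}); models not nested?")
    return float(stats.chi2.sf(2.0 * max(delta, 0.0), df))


def build_design(covariates: pd.DataFrame | None, add_intercept: bool = True) -> pd.DataFrame:
    """Numeric design matrix: categorical/string columns become reference-
    coded indicator columns; an intercept column ``const`` is prepended."""
    if covariates is None or covariates.shape[1] == 0:
        X = pd.DataFrame(index=covariates.index if covariates is not None else None)
    else:
        X = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = X.astype(float)
    if add_intercept:
        X.insert(0, "const", 1.0)
    return X


def gwas_scan(genotypes: GenotypeMatrix, outcome, covariates: pd.DataFrame | None = None,
              alpha: float = 5e-4) -> pd.DataFrame:
    """Additive-coding covariate-adjusted association scan.

    Per SNP, the minor-allele dosage (0/1/2) enters a logistic model on top
    of the covariates; the scan records the per-allele OR, Wald p and a
    pass flag at the screening threshold ``alpha``.  SNPs monomorphic on
    the complete cases, or with non-converged fits, are skipped with a
    reason.  Results are invariant to SNP ordering and row permutation.
    """
    y = np.asarray(outcome, dtype=float)
    if covariates is not None:
        covariates = covariates.copy()
        covariates.index = range(len(covariates))
    base = build_design(covariates) if covariates is not None else pd.DataFrame(
        {"const": np.ones(len(y))})
    base.index = range(len(y))
    cc_base = ~base.isna().any(axis=1).to_numpy() & ~np.isnan(y)

    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        g = genotypes.dosages[:, j]
        ok = cc_base & ~np.isnan(g)
        meta = genotypes.snps.loc[snp]
        rec = {"id": snp, "chrom": meta["chrom"], "pos": meta["pos"],
               "or": np.nan, "beta": np.nan, "se": np.nan, "p": np.nan,
               "pass": False, "note": ""}
        gg = g[ok]
        if gg.size == 0 or np.nanstd(gg) == 0:
            rec["note"] = "monomorphic"
            rows.append(rec)
            continue
        X = base.loc[ok].copy()
        X["dosage"] = gg
        fit = fit_logistic(y[ok], X)
        if not fit.converged:
            rec["note"] = "non-converged"
            rows.append(rec)
            continue
        res = wald_or(fit, "dosage")
        rec.update({"or": res.or_point, "beta": float(fit.params["dosage"]),
                    "se": float(fit.bse["dosage"]), "p": res.p,
                    "pass": bool(res.p < alpha)})
        rows.append(rec)
    return pd.DataFrame(rows).set_index("id")
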