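"""Lifestyle stratification, stratum-specific PRS odds ratios, interaction
tests, and the simplified dietary inflammatory index.

Continuous exposures are dichotomised at field cut points (low iff value <
cutoff, strictly): white blood cells < 4 x 10^9/L, coffee < 3 g/day, energy
< estimated need (100%), carbohydrate < 65 En%, protein < 13 En%, fat <
20 En%.  Smoking maps never-smokers vs former+current.  Within each stratum
level, adjusted odds ratios of the medium/high PRS categories against the
low-PRS reference come from a logistic model; the PRS x stratum interaction
is tested by a likelihood-ratio test on the product terms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import ORResult, build_design, fit_logistic, lrt, wald_or
from .dii_scores import DEFAULT_DII_SCORES
from .errors import (ConfigError, ConvergenceError, ParameterError,
                     UndefinedStatisticError)

__all__ = ["StratumDefinition", "InteractionTable", "dichotomize",
           "stratified_or", "interaction_pvalue", "compute_dii",
           "strata_presets", "cell_means_table"]


@dataclass
class StratumDefinition:
    """How one exposure is split into two strata.

    Numeric: ``low`` iff value < ``cutoff`` (strict).  Categorical: every
    observed level must appear in ``mapping`` (level -> stratum label).
    """

    variable: str
    cutoff: float | None = None
    labels: tuple = ("low", "high")
    mapping: dict | None = None
    units: str = ""

    def __post_init__(self):
        if (self.cutoff is None) == (self.mapping is None):
            raise ParameterError("give exactly one of cutoff (numeric) or mapping (categorical)")


def strata_presets() -> dict[str, StratumDefinition]:
    """The eight lifestyle stratifiers used in the worked analysis."""
    return {
        "wbc": StratumDefinition("wbc", cutoff=4.0, units="10^9/L"),
        "energy": StratumDefinition("energy_pct", cutoff=100.0, units="% of estimated need"),
        "carbohydrate": StratumDefinition("carb_enpct", cutoff=65.0, units="En%"),
        "protein": StratumDefinition("protein_enpct", cutoff=13.0, units="En%"),
        "fat": StratumDefinition("fat_enpct", cutoff=20.0, units="En%"),
        "exercise": StratumDefinition("activity", mapping={0: "no_exercise", 1: "exercise"},
                                      labels=("no_exercise", "exercise")),
        "smoking": StratumDefinition("smoking",
                                     mapping={"non": "non_smoke",
                                              "former": "smoke_former",
                                              "current": "smoke_former"},
                                     labels=("non_smoke", "smoke_former")),
        "coffee": StratumDefinition("coffee_g_day", cutoff=3.0, units="g/day"),
    }


def dichotomize(values: pd.Series, definition: StratumDefinition
                ) -> tuple[pd.Series, int]:
    """Stratum label per sample; returns (labels, n_excluded_missing)."""
    v = pd.Series(values)
    out = pd.Series(pd.NA, index=v.index, dtype="object")
    if definition.cutoff is not None:
        num = pd.to_numeric(v, errors="coerce")
        out[num < definition.cutoff] = definition.labels[0]
        out[num >= definition.cutoff] = definition.labels[1]
        n_excluded = int(num.isna().sum())
    else:
        known = v.isin(definition.mapping.keys())
        unknown = v[~known & v.notna()].unique()
        if len(unknown):
            raise ConfigError(
                f"{definition.variable}: levels without a stratum mapping: {list(unknown)}")
        out[known] = v[known].map(definition.mapping)
        n_excluded = int(v.isna().sum())
    cats = pd.Series(pd.Categorical(out, categories=list(dict.fromkeys(definition.labels))),
                     index=v.index, name=f"{definition.variable}_stratum")
    return cats, n_excluded


@dataclass
class InteractionTable:
    """Stratum-level x PRS-category adjusted ORs plus the interaction p."""

    cells: pd.DataFrame          # rows (stratum, prs_category): or, ci, p, estimable, note
    interaction_p: float
    reference: str = "within-stratum low-PRS"
    n_excluded: int = 0


def _complete_mask(*arrays) -> np.ndarray:
    m = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if isinstance(a, pd.DataFrame):
            m &= ~a.isna().any(axis=1).to_numpy()
        else:
            m &= ~pd.isna(np.asarray(a, dtype=object)).astype(bool)
    return m


def stratified_or(outcome, prs_categories: pd.Series, strata: pd.Series,
                  covariates: pd.DataFrame | None = None,
                  reference: str = "within") -> InteractionTable:
    """Adjusted ORs of medium/high PRS vs the low-PRS reference, by stratum.

    ``reference="within"`` (default) fits one logistic model per stratum
    level, so each level's low-PRS group is its own reference;
    ``reference="pooled"`` fits one model with stratum main effects, using
    the pooled low-PRS group as reference.  Cells that cannot be estimated
    (empty, single-class, or separated) are flagged, never fabricated.
    """
    if reference not in ("within", "pooled"):
        raise ParameterError("reference must be 'within' or 'pooled'")
    y = np.asarray(outcome, dtype=float)
    prs = pd.Series(prs_categories).reset_index(drop=True)
    strat = pd.Series(strata).reset_index(drop=True)
    cov = covariates.reset_index(drop=True) if covariates is not None else None

    ok = _complete_mask(pd.Series(y), prs, strat)
    if cov is not None:
        ok &= _complete_mask(cov)
    n_excluded = int((~ok).sum())
    levels = [l for l in strat.dropna().unique()]
    cat_levels = ["low", "medium", "high"]

    rows = []
    for level in levels:
        in_level = ok & (strat == level).to_numpy()
        yl = y[in_level]
        pl = prs[in_level]
        fit = None
        if reference == "within":
            X = pd.get_dummies(pl.astype(str), prefix="prs", dtype=float)
            X = X.reindex(columns=[f"prs_{c}" for c in cat_levels], fill_value=0.0)
            X = X.drop(columns="prs_low")
            if cov is not None:
                X = pd.concat([X.reset_index(drop=True),
                               build_design(cov[in_level].reset_index(drop=True),
                                            add_intercept=False).reset_index(drop=True)],
                              axis=1)
            X.insert(0, "const", 1.0)
            drop_const = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
            X = X.drop(columns=drop_const)
            if len(yl) > X.shape[1] and 0 < yl.sum() < len(yl):
                fit = fit_logistic(yl, X)
        for cat in cat_levels:
            n_cell = int(((pl == cat).to_numpy()).sum())
            rec = {"stratum": level, "prs_category": cat, "n": n_cell,
                   "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "p": np.nan, "estimable": False, "note": ""}
            if cat == "low":
                rec.update({"or": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                            "estimable": True, "note": "reference"})
            elif n_cell == 0:
                rec["note"] = "empty cell"
            elif fit is None or not fit.converged or f"prs_{cat}" not in fit.params.index:
                rec["note"] = "inestimable (non-converged or degenerate stratum)"
            else:
                res = wald_or(fit, f"prs_{cat}", reference_label="low-PRS")
                rec.update({"or": res.or_point, "ci_low": res.ci_low,
                            "ci_high": res.ci_high, "p": res.p, "estimable": True})
            rows.append(rec)

    if reference == "pooled":
        rows = _pooled_rows(y, prs, strat, cov, ok, levels, cat_levels)

    try:
        p_int = interaction_pvalue(y[ok], prs[ok], strat[ok],
                                   cov[ok].reset_index(drop=True) if cov is not None else None)
    except UndefinedStatisticError:
        p_int = np.nan  # single-level stratum: no interaction to test
    except ConvergenceError:
        p_int = np.nan  # separated/degenerate interaction fit: flagged, not faked
    cells = pd.DataFrame(rows).set_index(["stratum", "prs_category"])
    return InteractionTable(cells=cells, interaction_p=p_int,
                            reference=("within-stratum low-PRS" if reference == "within"
                                       else "pooled low-PRS"),
                            n_excluded=n_excluded)


def _pooled_rows(y, prs, strat, cov, ok, levels, cat_levels):
    """OR cells for the pooled-reference variant: one model, stratum x PRS
    indicator terms against the pooled low-PRS baseline."""
    rows = []
    yl = y[ok]
    pl, sl = prs[ok], strat[ok]
    X = pd.DataFrame({"const": np.ones(int(ok.sum()))})
    term_names = {}
    base_level = levels[0]
    for level in levels:
        if level != base_level:
            X[f"strat_{level}"] = (sl == level).to_numpy(dtype=float)
        for cat in cat_levels[1:]:
            name = f"prs_{cat}_x_{level}"
            X[name] = ((pl == cat) & (sl == level)).to_numpy(dtype=float)
            term_names[(level, cat)] = name
    if cov is not None:
        X = pd.concat([X.reset_index(drop=True),
                       build_design(cov[ok].reset_index(drop=True),
                                    add_intercept=False).reset_index(drop=True)], axis=1)
    X = X.drop(columns=[c for c in X.columns if c != "const" and X[c].nunique() <= 1])
    fit = fit_logistic(yl, X)
    for level in levels:
        for cat in cat_levels:
            n_cell = int(((pl == cat) & (sl == level)).sum())
            rec = {"stratum": level, "prs_category": cat, "n": n_cell,
                   "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                   "p": np.nan, "estimable": False, "note": ""}
            name = term_names.get((level, cat))
            if cat == "low":
                rec.update({"or": 1.0, "ci_low": 1.0, "ci_high": 1.0,
                            "estimable": True, "note": "pooled reference"})
            elif n_cell == 0:
                rec["note"] = "empty cell"
            elif not fit.converged or name not in fit.params.index:
                rec["note"] = "inestimable"
            else:
                res = wald_or(fit, name, reference_label="pooled low-PRS")
                rec.update({"or": res.or_point, "ci_low": res.ci_low,
                            "ci_high": res.ci_high, "p": res.p, "estimable": True})
            rows.append(rec)
    return rows


def interaction_pvalue(outcome, prs_categories, strata,
                       covariates: pd.DataFrame | None = None) -> float:
    """LRT p-value for PRS x stratum interaction in a logistic model.

    Full model: PRS-category indicators + stratum indicators + their
    products (+ covariates); reduced model drops the products.  Degrees of
    freedom = (n_categories - 1) x (n_levels - 1).
    """
    y = np.asarray(outcome, dtype=float)
    prs = pd.Series(prs_categories).reset_index(drop=True).astype(str)
    strat = pd.Series(strata).reset_index(drop=True).astype(str)
    cats = sorted(prs.unique())
    levels = sorted(strat.unique())
    if len(cats) < 2 or len(levels) < 2:
        raise UndefinedStatisticError(
            "interaction test needs both factors to vary "
            f"(PRS levels: {cats}, stratum levels: {levels})")

    X = pd.DataFrame({"const": np.ones(len(y))})
    for cat in cats[1:]:
        X[f"prs_{cat}"] = (prs == cat).to_numpy(dtype=float)
    for level in levels[1:]:
        X[f"strat_{level}"] = (strat == level).to_numpy(dtype=float)
    if covariates is not None:
        X = pd.concat([X, build_design(covariates.reset_index(drop=True),
                                       add_intercept=False)], axis=1)
    Xf = X.copy()
    for cat in cats[1:]:
        for level in levels[1:]:
            Xf[f"prs_{cat}_x_{level}"] = X[f"prs_{cat}"] * X[f"strat_{level}"]
    reduced = fit_logistic(y, X)
    full = fit_logistic(y, Xf)
    df = (len(cats) - 1) * (len(levels) - 1)
    return lrt(full, reduced, df)


def cell_means_table(outcome, prs_categories, strata) -> pd.DataFrame:
    """ANOVA-style cell report: outcome incidence per stratum x PRS cell
    (for comparability with incidence bar plots)."""
    df = pd.DataFrame({"y": np.asarray(outcome, dtype=float),
                       "prs": pd.Series(prs_categories).reset_index(drop=True),
                       "stratum": pd.Series(strata).reset_index(drop=True)})
    g = df.dropna().groupby(["stratum", "prs"], observed=True)["y"]
    out = g.agg(n="size", incidence="mean")
    return out


def compute_dii(intakes: pd.DataFrame, scores: dict[str, float] | None = None
                ) -> pd.Series:
    """Simplified dietary inflammatory index per sample.

    DII_i = sum_c(score_c * intake_ic) / 100 over the supplied components.
    Every intake column must have a score; a component without one raises,
    naming the component.
    """
    scores = scores if scores is not None else DEFAULT_DII_SCORES
    missing = [c for c in intakes.columns if c not in scores]
    if missing:
        raise ConfigError(f"no inflammatory score for component(s): {', '.join(missing)}")
    weights = np.array([scores[c] for c in intakes.columns], dtype=float)
    vals = intakes.to_numpy(dtype=float) @ weights / 100.0
    return pd.Series(vals, index=intakes.index, name="dii")
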