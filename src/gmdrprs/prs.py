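"""Risk-allele assignment and risk-allele-count polygenic risk scores.

The PRS of a sample is the integer count of risk alleles over the
best-model SNPs: per SNP the risk allele is the one whose additive dosage
carries OR > 1 in the adjusted association scan (the minor allele when
OR > 1, otherwise the major allele), and a genotype contributes 0, 1 or 2
copies of it.  Scores are stratified into low/medium/high either at fixed
cut points — the shipped replication preset uses (6, 8), i.e. 0-6 / 7-8 /
>=9 for an eight-SNP model — or at empirical tertiles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .errors import ParameterError, UndefinedStatisticError

__all__ = ["RiskAlleleMap", "PRSProfile", "assign_risk_alleles",
           "compute_prs", "categorize_prs", "PRESET_CUT_POINTS"]

# Named cut-point presets; "gc8" pins the 0-6 / 7-8 / >=9 tertile
# boundaries of the eight-SNP gastric-cancer model.
PRESET_CUT_POINTS = {"gc8": (6, 8)}


@dataclass
class RiskAlleleMap:
    """Per-SNP risk-allele assignment with its source odds ratio."""

    table: pd.DataFrame  # index snp id: risk_allele, other_allele, source_or, direction

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table.index)

    def risk_allele(self, snp: str) -> str:
        return self.table.loc[snp, "risk_allele"]


@dataclass
class PRSProfile:
    """Per-sample integer PRS with category labels.

    ``scores`` is float so excluded samples can carry NaN; ``included``
    flags samples scored over every mapped SNP.
    """

    scores: pd.Series
    categories: pd.Series | None
    cut_points: tuple | None
    k: int
    included: pd.Series = None


def assign_risk_alleles(gwas: pd.DataFrame, snp_ids, snps_meta: pd.DataFrame
                        ) -> RiskAlleleMap:
    """Choose each SNP's risk allele from its adjusted additive OR.

    OR > 1: the minor (coded) allele is the risk allele; OR < 1: the major
    allele.  OR exactly 1 leaves the direction undefined and raises.
    """
    rows = []
    for snp in snp_ids:
        if snp not in gwas.index or pd.isna(gwas.loc[snp, "or"]):
            raise ParameterError(f"no association OR available for {snp!r}")
        or_ = float(gwas.loc[snp, "or"])
        minor = snps_meta.loc[snp, "minor_allele"]
        major = snps_meta.loc[snp, "major_allele"]
        if or_ == 1.0:
            raise UndefinedStatisticError(
                f"{snp}: OR is exactly 1; risk-allele direction ambiguous")
        if or_ > 1.0:
            risk, other, direction = minor, major, "minor_is_risk"
        else:
            risk, other, direction = major, minor, "major_is_risk"
        rows.append({"id": snp, "risk_allele": risk, "other_allele": other,
                     "source_or": or_, "direction": direction})
    return RiskAlleleMap(pd.DataFrame(rows).set_index("id"))


def compute_prs(genotypes: GenotypeMatrix, risk_map: RiskAlleleMap,
                missing_policy: str = "exclude") -> PRSProfile:
    """Sum risk-allele counts over the mapped SNPs.

    Per SNP the count is the minor-allele dosage when the minor allele is
    the risk allele, else ``2 - dosage``.  Missing genotypes follow
    ``missing_policy``: ``"exclude"`` (default) flags the sample and leaves
    its score NaN; ``"impute"`` substitutes the expected risk-allele dosage
    (2 x risk-allele frequency among called samples), yielding a non-integer
    score for affected samples.
    """
    if missing_policy not in ("exclude", "impute"):
        raise ParameterError("missing_policy must be 'exclude' or 'impute'")
    missing_snps = [s for s in risk_map.snp_ids if s not in genotypes.snp_ids]
    if missing_snps:
        raise ParameterError(f"genotypes lack mapped SNPs: {', '.join(missing_snps)}")

    n = genotypes.n_samples
    total = np.zeros(n)
    any_missing = np.zeros(n, dtype=bool)
    for snp in risk_map.snp_ids:
        d = genotypes.column(snp)
        direction = risk_map.table.loc[snp, "direction"]
        risk_dosage = d if direction == "minor_is_risk" else 2.0 - d
        miss = np.isnan(risk_dosage)
        any_missing |= miss
        if missing_policy == "impute" and miss.any():
            risk_dosage = risk_dosage.copy()
            risk_dosage[miss] = np.nanmean(risk_dosage)
        total += risk_dosage
    included = ~any_missing if missing_policy == "exclude" else np.ones(n, dtype=bool)
    scores = total.copy()
    if missing_policy == "exclude":
        scores[any_missing] = np.nan
    return PRSProfile(
        scores=pd.Series(scores, index=genotypes.sample_ids, name="prs"),
        categories=None, cut_points=None, k=len(risk_map.snp_ids),
        included=pd.Series(included, index=genotypes.sample_ids, name="included"))


def categorize_prs(scores: pd.Series, cut_points=(6, 8)) -> tuple[pd.Series, tuple, pd.Series]:
    """Stratify PRS values into low/medium/high.

    ``cut_points`` is either ``(c1, c2)`` — low: score <= c1, medium:
    c1 < score <= c2, high: score > c2 — or the string ``"tertile"``, which
    places the cuts at the empirical 1/3 and 2/3 quantiles with ties
    assigned to the lower category.  Returns (categories, realized cut
    points, realized group sizes); NaN scores stay uncategorised.
    """
    s = pd.Series(scores).astype(float)
    valid = s.dropna()
    if valid.empty:
        raise ParameterError("no scored samples to categorise")
    if isinstance(cut_points, str):
        if cut_points != "tertile":
            raise ParameterError(f"unknown cut-point mode {cut_points!r}")
        c1, c2 = np.quantile(valid, [1 / 3, 2 / 3])
        if c1 == c2:
            raise UndefinedStatisticError(
                "degenerate score distribution: tertile cut points coincide "
                f"(both {c1}); use fixed cut points instead")
    else:
        c1, c2 = cut_points
        if not c1 < c2:
            raise ParameterError("cut points must satisfy c1 < c2")
    cats = pd.Series(pd.NA, index=s.index, dtype="object")
    cats[s <= c1] = "low"
    cats[(s > c1) & (s <= c2)] = "medium"
    cats[s > c2] = "high"
    cats = pd.Series(pd.Categorical(cats, categories=["low", "medium", "high"],
                                    ordered=True), index=s.index, name="prs_category")
    sizes = cats.value_counts().reindex(["low", "medium", "high"]).fillna(0).astype(int)
    return cats, (float(c1), float(c2)), sizes
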