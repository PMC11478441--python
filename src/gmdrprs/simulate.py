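"""Synthetic case-control cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* genotypes drawn under Hardy-Weinberg equilibrium at configurable minor
  allele frequencies, with optional pairwise linkage disequilibrium
  (parameterised by D', the normalised LD coefficient) and optional
  completely-at-random missingness;
* covariates and lifestyle exposures (age, sex, BMI, smoking, white blood
  cell count, coffee intake, macronutrient energy fractions, per-component
  dietary intakes) drawn from simple parametric families whose defaults
  mimic a Korean adult health-examinee cohort with a rare (<1%) gastric
  cancer outcome;
* a binary outcome generated from one logistic linear predictor that
  composes additive per-SNP effects, 3x3 per-cell epistatic log-odds
  offsets, covariate effects and gene-environment product terms, so that
  planted effects are recoverable by the same logistic machinery the
  analysis uses.

Reproducibility contract: every public generator takes an integer seed and
identical (configuration, seed) yields a bit-identical result.  Draw order
is documented per function.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (CohortDataset, GenotypeMatrix, TruthRecord,
                        default_snp_meta)
from .dii_scores import TYPICAL_DAILY_INTAKE
from .errors import ConfigError, ParameterError

__all__ = [
    "SNPSpec", "GxETerm", "EffectModel",
    "simulate_genotypes", "simulate_exposures", "simulate_outcome",
    "simulate_cohort", "simulate_case_control",
    "default_exposure_config", "table3_snp_specs", "checkerboard_epistasis",
]


@dataclass
class SNPSpec:
    """Specification of one simulated SNP.

    ``ld_partner``/``ld_dprime`` couple this SNP to a previously declared,
    itself-unpartnered SNP: the two-locus haplotype distribution is chosen
    so the minor alleles co-occur with normalised coefficient D' =
    ``ld_dprime`` (positive coupling).
    """

    id: str
    maf: float
    ld_partner: str | None = None
    ld_dprime: float | None = None
    missing_rate: float = 0.0
    chrom: str = "1"
    pos: int | None = None
    minor_allele: str = "A"
    major_allele: str = "G"

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ParameterError(f"{self.id}: maf must be in (0, 0.5], got {self.maf}")
        if (self.ld_partner is None) != (self.ld_dprime is None):
            raise ParameterError(f"{self.id}: ld_partner and ld_dprime must be given together")
        if self.ld_dprime is not None and not (0.0 <= self.ld_dprime <= 1.0):
            raise ParameterError(
                f"{self.id}: requested D'={self.ld_dprime} outside the admissible range [0, 1]"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError(f"{self.id}: missing_rate must be in [0, 1)")


@dataclass
class GxETerm:
    """One gene-environment product term in the linear predictor.

    The genetic part is a weighted sum of minor-allele dosages
    (``snp_weights``); the environmental part is a numeric exposure column.
    """

    snp_weights: dict[str, float]
    exposure: str
    beta: float


@dataclass
class EffectModel:
    """Logistic data-generating model: eta = intercept + additive +
    epistasis-cell offsets + covariate effects + G x E products."""

    intercept: float = 0.0
    additive_betas: dict[str, float] = field(default_factory=dict)
    # (snp_a, snp_b) -> 3x3 array of log-odds offsets indexed by (dosage_a, dosage_b)
    epistasis_cells: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    covariate_betas: dict[str, float] = field(default_factory=dict)
    gxe_terms: list[GxETerm] = field(default_factory=list)

    def __post_init__(self):
        vals = [self.intercept, *self.additive_betas.values(), *self.covariate_betas.values()]
        vals += [t.beta for t in self.gxe_terms]
        for pair, cells in self.epistasis_cells.items():
            cells = np.asarray(cells, dtype=float)
            if cells.shape != (3, 3):
                raise ParameterError(f"epistasis cells for {pair} must be 3x3")
            self.epistasis_cells[pair] = cells
            vals += list(cells.ravel())
        if not np.all(np.isfinite(vals)):
            raise ParameterError("all model coefficients must be finite")


def _haplotype_freqs(p_a: float, p_b: float, dprime: float) -> tuple[float, float]:
    """(f_ab, D) for minor alleles a, b given D' with positive coupling."""
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    d = dprime * d_max
    return p_a * p_b + d, d


def simulate_genotypes(specs: list[SNPSpec], n: int, seed: int) -> GenotypeMatrix:
    """Draw HWE genotypes (with optional pairwise LD and missingness).

    Draw order (fixed, documented): SNPs are processed in declaration
    order.  An unpartnered SNP consumes two Bernoulli(maf) haplotype draws
    of length ``n``; a partnered SNP consumes two uniform draws of length
    ``n`` (conditional haplotype sampling given the partner's haplotypes).
    After all genotypes, one uniform draw of length ``n`` per SNP with
    ``missing_rate > 0``, again in declaration order.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not specs:
        raise ParameterError("specs must be non-empty")
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate SNP ids in specs")
    by_id = {s.id: s for s in specs}

    rng = np.random.default_rng(seed)
    haplotypes: dict[str, np.ndarray] = {}   # id -> (2, n) 0/1 minor-allele indicators
    dosages = np.empty((n, len(specs)), dtype=float)

    for j, spec in enumerate(specs):
        if spec.ld_partner is None:
            haps = (rng.random((2, n)) < spec.maf).astype(np.int8)
        else:
            partner = by_id.get(spec.ld_partner)
            if partner is None:
                raise ParameterError(f"{spec.id}: unknown ld_partner {spec.ld_partner!r}")
            if partner.ld_partner is not None:
                raise ParameterError(f"{spec.id}: ld_partner must itself be unpartnered")
            if spec.ld_partner not in haplotypes:
                raise ParameterError(f"{spec.id}: ld_partner must be declared before this SNP")
            p_a, p_b = partner.maf, spec.maf
            f_ab, _ = _haplotype_freqs(p_a, p_b, spec.ld_dprime)
            # conditional minor-allele probability for b given partner haplotype a
            p_b_given_a1 = f_ab / p_a
            p_b_given_a0 = (p_b - f_ab) / (1 - p_a)
            part = haplotypes[spec.ld_partner]
            u = rng.random((2, n))
            probs = np.where(part == 1, p_b_given_a1, p_b_given_a0)
            haps = (u < probs).astype(np.int8)
        haplotypes[spec.id] = haps
        dosages[:, j] = haps.sum(axis=0)

    for j, spec in enumerate(specs):
        if spec.missing_rate > 0:
            mask = rng.random(n) < spec.missing_rate
            dosages[mask, j] = np.nan

    meta = pd.DataFrame(
        {
            "chrom": [s.chrom for s in specs],
            "pos": [s.pos if s.pos is not None else 1000 + 1000 * j
                    for j, s in enumerate(specs)],
            "minor_allele": [s.minor_allele for s in specs],
            "major_allele": [s.major_allele for s in specs],
        },
        index=ids,
    )
    samples = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(dosages, ids, samples, meta)


def default_exposure_config() -> dict:
    """Default exposure/covariate distributions for the synthetic cohort.

    Continuous summaries mirror a middle-aged Korean health-examinee
    population: WBC ~ N(5.7, 1.55^2) 10^9/L, BMI ~ N(24.0, 2.9^2) kg/m^2,
    age ~ N(53.5, 8.0^2) years truncated at 40, energy intake expressed as
    percent of estimated need ~ N(98.7, 31.5^2), macronutrient energy
    fractions near 71.5/13.5/14.0 En% (carbohydrate/protein/fat), smoking
    status 73/16/11% never/former/current, coffee intake a zero-inflated
    gamma in g/day with roughly a third of subjects below 3 g/day, and
    38 dietary-component intakes as gamma variables around typical adult
    daily means.
    """
    cfg: dict[str, dict] = {
        "age": {"dist": "truncnormal", "mean": 53.5, "sd": 8.0, "lower": 40.0},
        "sex": {"dist": "categorical", "levels": [0, 1], "probs": [0.65, 0.35]},
        "bmi": {"dist": "normal", "mean": 24.0, "sd": 2.9},
        "residence": {"dist": "categorical", "levels": ["urban", "rural"],
                      "probs": [0.8, 0.2]},
        "activity": {"dist": "categorical", "levels": [0, 1], "probs": [0.458, 0.542]},
        "education": {"dist": "categorical",
                      "levels": ["lt_high_school", "high_school", "college"],
                      "probs": [0.297, 0.434, 0.269]},
        "income": {"dist": "categorical", "levels": ["low", "medium", "high"],
                   "probs": [0.305, 0.611, 0.084]},
        "smoking": {"dist": "categorical", "levels": ["non", "former", "current"],
                    "probs": [0.731, 0.156, 0.113]},
        "alcohol": {"dist": "categorical", "levels": [0, 1], "probs": [0.952, 0.048]},
        "energy_pct": {"dist": "normal", "mean": 98.7, "sd": 31.5},
        "carb_enpct": {"dist": "normal", "mean": 71.5, "sd": 7.0},
        "protein_enpct": {"dist": "normal", "mean": 13.45, "sd": 2.6},
        "fat_enpct": {"dist": "normal", "mean": 14.0, "sd": 5.4},
        "wbc": {"dist": "normal", "mean": 5.7, "sd": 1.55},
        "coffee_g_day": {"dist": "zigamma", "p_zero": 0.15, "shape": 1.3, "scale": 4.0},
    }
    for comp, mean in TYPICAL_DAILY_INTAKE.items():
        cfg[f"intake_{comp}"] = {"dist": "gamma", "shape": 4.0, "scale": mean / 4.0}
    return cfg


_DISTS = {"normal", "truncnormal", "gamma", "zigamma", "categorical"}


def _draw(rng: np.random.Generator, n: int, name: str, spec: dict):
    dist = spec.get("dist")
    if dist not in _DISTS:
        raise ConfigError(f"exposure {name!r}: unknown distribution {dist!r}")
    if dist == "normal":
        return rng.normal(spec["mean"], spec["sd"], size=n)
    if dist == "truncnormal":
        lo = spec.get("lower", -np.inf)
        x = rng.normal(spec["mean"], spec["sd"], size=n)
        while True:  # redraw below the bound; fine for mild truncation
            bad = x < lo
            if not bad.any():
                return x
            x[bad] = rng.normal(spec["mean"], spec["sd"], size=int(bad.sum()))
    if dist == "gamma":
        return rng.gamma(spec["shape"], spec["scale"], size=n)
    if dist == "zigamma":
        p0 = spec["p_zero"]
        if not (0.0 <= p0 <= 1.0):
            raise ConfigError(f"exposure {name!r}: p_zero must be in [0, 1]")
        zero = rng.random(n) < p0
        x = rng.gamma(spec["shape"], spec["scale"], size=n)
        x[zero] = 0.0
        return x
    # categorical
    levels, probs = spec["levels"], np.asarray(spec["probs"], dtype=float)
    if len(levels) != len(probs) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError(f"exposure {name!r}: levels/probs mismatch or probs do not sum to 1")
    idx = rng.choice(len(levels), size=n, p=probs)
    return np.asarray(levels, dtype=object)[idx]


def simulate_exposures(n: int, config: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw the per-sample covariate/exposure/intake table.

    Draw order: one vectorised draw per exposure, in the configuration's
    insertion order.  ``config`` defaults to :func:`default_exposure_config`.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    config = config if config is not None else default_exposure_config()
    rng = np.random.default_rng(seed)
    cols = {name: _draw(rng, n, name, spec) for name, spec in config.items()}
    df = pd.DataFrame(cols, index=[f"S{i:06d}" for i in range(n)])
    return df


def simulate_outcome(genotypes: GenotypeMatrix, exposures: pd.DataFrame,
                     model: EffectModel, seed: int = 0) -> tuple[np.ndarray, TruthRecord]:
    """Bernoulli outcome from the logistic linear predictor of ``model``.

    Missing dosages contribute their SNP's mean observed dosage to additive
    terms and a zero offset to epistasis cells, so missingness never makes
    eta non-finite.  Draw order: a single binomial draw of length n.
    """
    n = genotypes.n_samples
    eta = np.full(n, float(model.intercept))

    def dosage(snp):
        if snp not in genotypes.snp_ids:
            raise ParameterError(f"model references unknown SNP {snp!r}")
        col = genotypes.column(snp)
        m = np.isnan(col)
        if m.any():
            col[m] = np.nanmean(col)
        return col

    for snp, beta in model.additive_betas.items():
        eta += beta * dosage(snp)
    for (a, b), cells in model.epistasis_cells.items():
        ga, gb = genotypes.column(a), genotypes.column(b)
        ok = ~(np.isnan(ga) | np.isnan(gb))
        eta[ok] += cells[ga[ok].astype(int), gb[ok].astype(int)]
    for cov, beta in model.covariate_betas.items():
        if cov not in exposures.columns:
            raise ParameterError(f"model references unknown covariate {cov!r}")
        eta += beta * exposures[cov].to_numpy(dtype=float)
    for term in model.gxe_terms:
        if term.exposure not in exposures.columns:
            raise ParameterError(f"G x E term references unknown exposure {term.exposure!r}")
        score = np.zeros(n)
        for snp, w in term.snp_weights.items():
            score += w * dosage(snp)
        eta += term.beta * score * exposures[term.exposure].to_numpy(dtype=float)

    if not np.all(np.isfinite(eta)):
        raise ParameterError("non-finite linear predictor eta")
    rng = np.random.default_rng(seed)
    y = rng.binomial(1, expit(eta)).astype(int)

    risk_alleles = {}
    for snp, beta in model.additive_betas.items():
        meta = genotypes.snps.loc[snp]
        risk_alleles[snp] = meta["minor_allele"] if beta > 0 else meta["major_allele"]
    truth = TruthRecord(planted_pairs=list(model.epistasis_cells.keys()),
                        risk_alleles=risk_alleles, seed=seed)
    return y, truth


def _child_seeds(seed: int, k: int) -> list[int]:
    """Independent sub-stream seeds (< 2**31) derived from one master seed."""
    return [int(s % (2 ** 31)) for s in np.random.SeedSequence(seed).generate_state(k)]


def simulate_cohort(specs: list[SNPSpec], n: int, model: EffectModel, seed: int = 0,
                    exposure_config: dict | None = None) -> CohortDataset:
    """One-call cohort: genotypes + exposures + outcome, reproducibly.

    Three independent sub-streams (genotypes, exposures, outcome) are
    derived from ``seed`` so that re-running a single stage with the same
    master seed reproduces that stage exactly.
    """
    s_g, s_e, s_y = _child_seeds(seed, 3)
    gm = simulate_genotypes(specs, n, s_g)
    expo = simulate_exposures(n, exposure_config, s_e)
    y, truth = simulate_outcome(gm, expo, model, s_y)
    truth.seed = seed
    table = expo.copy()
    table.insert(0, "outcome", y)
    return CohortDataset(gm, table, truth)


def simulate_case_control(n_cases: int, n_controls: int, specs: list[SNPSpec],
                          model: EffectModel, seed: int = 0,
                          exposure_config: dict | None = None,
                          batch_size: int = 20000, max_batches: int = 200) -> CohortDataset:
    """Fixed-quota case-control design.

    Population batches are simulated under ``model`` until ``n_cases``
    cases and ``n_controls`` controls have accumulated; the first samples
    of each class (in generation order) are retained.  Raises if the quota
    is unreachable within ``max_batches`` batches.
    """
    seeds = _child_seeds(seed, max_batches)
    case_rows, control_rows = [], []
    geno_parts, table_parts = [], []
    truth = None
    offset = 0
    for b in range(max_batches):
        ds = simulate_cohort(specs, batch_size, model, seeds[b],
                             exposure_config=exposure_config)
        truth = truth or ds.truth
        y = ds.outcome
        case_rows.extend((offset + i) for i in np.flatnonzero(y == 1))
        control_rows.extend((offset + i) for i in np.flatnonzero(y == 0))
        geno_parts.append(ds.genotypes.dosages)
        table_parts.append(ds.table)
        offset += batch_size
        if len(case_rows) >= n_cases and len(control_rows) >= n_controls:
            break
    else:
        raise ParameterError(
            f"could not reach {n_cases} cases / {n_controls} controls in "
            f"{max_batches} batches of {batch_size}; raise the batch budget or prevalence"
        )
    keep = np.array(sorted(case_rows[:n_cases] + control_rows[:n_controls]))
    dosages = np.vstack(geno_parts)[keep]
    table = pd.concat(table_parts, ignore_index=True).iloc[keep].reset_index(drop=True)
    samples = [f"S{i:06d}" for i in range(len(keep))]
    table.index = samples
    gm = GenotypeMatrix(dosages, [s.id for s in specs], samples,
                        default_snp_meta([s.id for s in specs]))
    # keep declared metadata (alleles, positions) from the specs
    gm.snps = pd.DataFrame(
        {"chrom": [s.chrom for s in specs],
         "pos": [s.pos if s.pos is not None else 1000 + 1000 * j
                 for j, s in enumerate(specs)],
         "minor_allele": [s.minor_allele for s in specs],
         "major_allele": [s.major_allele for s in specs]},
        index=[s.id for s in specs])
    truth.seed = seed
    return CohortDataset(gm, table, truth)


def table3_snp_specs() -> list[SNPSpec]:
    """The ten-SNP panel used throughout the worked examples: minor allele
    frequencies of the ten gastric-cancer-associated loci the pipeline was
    designed around (DAB1, PDK1, DOCK10, ZBTB20, KALRN, ADAM29, MAGI2,
    CSMD1, MICAL2, CSNK2A1 variants)."""
    rows = [
        ("rs7521784", "1", 58175325, "A", "G", 0.4178),
        ("rs12693006", "2", 173467213, "C", "T", 0.2374),
        ("rs1045653", "2", 225630435, "T", "C", 0.3389),
        ("rs9835646", "3", 114148557, "A", "C", 0.196),
        ("rs630760", "3", 124149174, "G", "A", 0.1762),
        ("rs11946315", "4", 175870844, "C", "T", 0.2759),
        ("rs1207808", "7", 78496427, "C", "G", 0.2762),
        ("rs58499534", "8", 3471561, "G", "A", 0.2156),
        ("rs10831776", "11", 12297403, "G", "A", 0.2622),
        ("rs205881", "20", 486771, "T", "C", 0.2407),
    ]
    return [SNPSpec(id=r[0], chrom=r[1], pos=r[2], minor_allele=r[3],
                    major_allele=r[4], maf=r[5]) for r in rows]


def checkerboard_epistasis(strength: float = math.log(3.5)) -> np.ndarray:
    """3x3 log-odds offset table with a checkerboard (parity) pattern.

    Cells where the two dosages have equal parity get ``+strength``; the
    others get 0, giving an ``exp(strength)``-fold odds contrast between
    adjacent cells and a purely non-additive joint effect.
    """
    cells = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if (i + j) % 2 == 0:
                cells[i, j] = strength
    return cells
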