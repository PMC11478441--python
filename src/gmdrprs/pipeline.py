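"""End-to-end pipeline: QC -> GWAS screen -> LD pruning -> GMDR search ->
PRS -> stratified interaction analysis, with per-stage outputs and a run
manifest for reproducibility."""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import COVARIATE_SETS, gwas_scan
from .config import PipelineConfig, config_hash
from .datatypes import CohortDataset
from .errors import ConfigError, UndefinedStatisticError
from .gmdr import GMDRSearchResult, gmdr_search, make_cv_plan, search_table
from .gxe import compute_dii, dichotomize, strata_presets, stratified_or
from .io import (read_genotypes, read_phenotypes, write_dosage_tsv,
                 write_json, write_phenotypes, write_truth)
from .prs import assign_risk_alleles, categorize_prs, compute_prs
from .qc import apply_qc, dprime_matrix, ld_prune
from .simulate import EffectModel, GxETerm, SNPSpec, simulate_cohort

log = logging.getLogger("gmdrprs")

__all__ = ["run_pipeline", "PipelineResult", "effect_model_from_dict"]


def effect_model_from_dict(d: dict) -> EffectModel:
    """Build an EffectModel from its YAML-friendly dict form (epistasis
    pairs as ``{snps: [a, b], cells: 3x3 list}`` entries)."""
    epi = {}
    for entry in d.get("epistasis", []):
        a, b = entry["snps"]
        epi[(a, b)] = np.asarray(entry["cells"], dtype=float)
    gxe = [GxETerm(snp_weights=t["snp_weights"], exposure=t["exposure"],
                   beta=float(t["beta"]))
           for t in d.get("gxe", [])]
    return EffectModel(intercept=float(d.get("intercept", 0.0)),
                       additive_betas=dict(d.get("additive", {})),
                       epistasis_cells=epi,
                       covariate_betas=dict(d.get("covariates", {})),
                       gxe_terms=gxe)


@dataclass
class PipelineResult:
    manifest: dict
    cohort: CohortDataset
    qc_report: object
    gwas: pd.DataFrame
    candidates: list
    search: GMDRSearchResult | None
    prs_scores: pd.Series | None
    prs_categories: pd.Series | None
    interactions: dict = field(default_factory=dict)


def _covariate_frame(table: pd.DataFrame, covariate_set: str) -> pd.DataFrame | None:
    cols = [c for c in COVARIATE_SETS.get(covariate_set, []) if c in table.columns]
    return table[cols] if cols else None


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute every stage in order, persisting outputs and a manifest.

    Stage order: cohort (simulate or load) -> SNP QC -> covariate-adjusted
    GWAS -> D' pruning of screened SNPs -> exhaustive GMDR search -> PRS
    over the best model -> lifestyle-stratified ORs and interaction tests
    -> DII.  Any stage error halts the run with the stage name; outputs of
    completed stages stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "config_sha256": config_hash(config),
                      "seed": config.seed, "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": {}}
    t = lambda: time.strftime("%Y-%m-%dT%H:%M:%S")

    # -- cohort -----------------------------------------------------------
    stage = "cohort"
    if config.paths.get("genotypes"):
        table = read_phenotypes(config.paths["phenotypes"])
        gm = read_genotypes(config.paths["genotypes"],
                            sample_ids=list(table.index))
        cohort = CohortDataset(gm, table, None)
    else:
        if not config.snps:
            raise ConfigError("config needs either paths.genotypes or a snps list")
        specs = [SNPSpec(**s) for s in config.snps]
        model = effect_model_from_dict(config.effect_model)
        cohort = simulate_cohort(specs, config.n_samples, model, config.seed,
                                 exposure_config=config.exposures)
        write_dosage_tsv(cohort.genotypes, outdir / "genotypes.tsv")
        write_phenotypes(cohort.table, outdir / "phenotypes.tsv")
        write_truth(cohort.truth, outdir / "truth.json")
    y = cohort.outcome
    manifest["stages"][stage] = {"n_samples": cohort.genotypes.n_samples,
                                 "n_snps": cohort.genotypes.n_snps,
                                 "n_cases": int(y.sum()), "at": t()}
    log.info("cohort: %d samples (%d cases), %d SNPs",
             len(y), int(y.sum()), cohort.genotypes.n_snps)

    # -- QC ---------------------------------------------------------------
    gm_qc, report = apply_qc(cohort.genotypes, config.qc)
    report.table.to_csv(outdir / "qc_report.tsv", sep="\t")
    write_json({"n_input": report.n_input, "n_kept": report.n_kept,
                "n_removed": report.n_removed}, outdir / "qc_summary.json")
    manifest["stages"]["qc"] = {"in": report.n_input, "kept": report.n_kept, "at": t()}
    log.info("qc: kept %d / %d SNPs", report.n_kept, report.n_input)

    # -- GWAS screen ------------------------------------------------------
    covars = _covariate_frame(cohort.table, config.covariate_set)
    gwas = gwas_scan(gm_qc, y, covars, alpha=config.gwas_alpha)
    gwas.to_csv(outdir / "gwas.tsv", sep="\t")
    screened = list(gwas.index[gwas["pass"]])
    manifest["stages"]["gwas"] = {"n_tested": len(gwas),
                                  "n_pass": len(screened), "at": t()}
    log.info("gwas: %d / %d SNPs below alpha=%g", len(screened), len(gwas),
             config.gwas_alpha)

    # -- LD pruning -------------------------------------------------------
    candidates = screened if len(screened) >= 2 else list(gwas.index[~gwas["or"].isna()])
    if len(candidates) >= 2:
        dp = dprime_matrix(gm_qc, candidates)
        positions = {s: (gwas.loc[s, "chrom"], gwas.loc[s, "pos"]) for s in candidates}
        candidates = ld_prune(candidates, dp, gwas["p"].to_dict(),
                              threshold=config.ld_threshold, positions=positions)
    manifest["stages"]["prune"] = {"n_candidates": len(candidates), "at": t()}
    log.info("prune: %d candidate SNPs after D' >= %.2f pruning",
             len(candidates), config.ld_threshold)

    # -- GMDR search ------------------------------------------------------
    search = None
    if len(candidates) >= 1:
        ks = tuple(k for k in config.k_range if 1 <= k <= len(candidates))
        plan = make_cv_plan(y, n_folds=config.n_folds, seed=config.seed)
        search = gmdr_search(gm_qc, y, covars, candidates=candidates, k_range=ks,
                             plan=plan, threshold=config.gmdr_threshold,
                             budget=config.budget)
        search_table(search).to_csv(outdir / "gmdr_models.tsv", sep="\t")
        write_json({"snp_ids": list(search.best.snp_ids), "trba": search.best.trba,
                    "teba": search.best.teba,
                    "cvc": f"{search.best.cvc}/{search.best.n_folds}",
                    "signed_rank_p": search.best.signed_rank_p},
                   outdir / "gmdr_best.json")
        manifest["stages"]["gmdr"] = {"n_evaluated": search.n_evaluated,
                                      "best": list(search.best.snp_ids), "at": t()}
        log.info("gmdr: best model %s (CVC %d/%d, p=%.3g)", search.best.snp_ids,
                 search.best.cvc, search.best.n_folds, search.best.signed_rank_p)

    # -- PRS --------------------------------------------------------------
    prs_scores = prs_cats = None
    if search is not None:
        risk_map = assign_risk_alleles(gwas, search.best.snp_ids, gm_qc.snps)
        risk_map.table.to_csv(outdir / "risk_alleles.tsv", sep="\t")
        profile = compute_prs(gm_qc, risk_map, missing_policy=config.prs_missing_policy)
        prs_scores = profile.scores
        cut = config.prs_cut_points
        if not isinstance(cut, str):
            cmax = 2 * len(search.best.snp_ids)
            if cut[0] >= cmax:
                cut = "tertile"  # fixed preset meaningless for tiny models
        try:
            prs_cats, realized_cuts, sizes = categorize_prs(prs_scores, cut)
        except UndefinedStatisticError:
            # discrete score piles on few values; fall back to median +/- 1
            m = int(np.nanmedian(prs_scores))
            fallback = (m - 1, m) if m >= 1 else (m, m + 1)
            prs_cats, realized_cuts, sizes = categorize_prs(prs_scores, fallback)
        out = pd.DataFrame({"prs": prs_scores, "category": prs_cats.astype(str)})
        out.index.name = "sample_id"
        out.to_csv(outdir / "prs.tsv", sep="\t")
        manifest["stages"]["prs"] = {"cut_points": list(realized_cuts),
                                     "sizes": sizes.to_dict(), "at": t()}
        log.info("prs: cuts %s, group sizes %s", realized_cuts, sizes.to_dict())

    # -- stratified interaction analysis ---------------------------------
    interactions = {}
    if prs_cats is not None:
        presets = strata_presets()
        for name in config.strata:
            if name not in presets:
                raise ConfigError(f"unknown stratum preset {name!r}")
            defn = presets[name]
            if defn.variable not in cohort.table.columns:
                log.info("stratum %s skipped: column %s absent", name, defn.variable)
                continue
            labels, _ = dichotomize(cohort.table[defn.variable], defn)
            # the stratifier cannot also be an adjustment covariate
            cov_s = (covars.drop(columns=[defn.variable], errors="ignore")
                     if covars is not None else None)
            if cov_s is not None and cov_s.shape[1] == 0:
                cov_s = None
            try:
                tab = stratified_or(y, prs_cats.reset_index(drop=True),
                                    labels.reset_index(drop=True), cov_s)
            except Exception as e:  # degenerate strata in tiny demos
                log.warning("stratum %s inestimable: %s", name, e)
                continue
            interactions[name] = tab
            tab.cells.to_csv(outdir / f"interaction_{name}.tsv", sep="\t")
        write_json({k: v.interaction_p for k, v in interactions.items()},
                   outdir / "interaction_pvalues.json")
        manifest["stages"]["gxe"] = {"strata": list(interactions), "at": t()}

    # -- DII --------------------------------------------------------------
    intake_cols = [c for c in cohort.table.columns if c.startswith("intake_")]
    if intake_cols:
        intakes = cohort.table[intake_cols].rename(
            columns=lambda c: c.removeprefix("intake_"))
        dii = compute_dii(intakes)
        dii.to_frame().rename_axis("sample_id").to_csv(outdir / "dii.tsv", sep="\t")
        manifest["stages"]["dii"] = {"n": len(dii), "mean": float(dii.mean()), "at": t()}

    manifest["finished"] = t()
    write_json(manifest, outdir / "manifest.json")
    return PipelineResult(manifest=manifest, cohort=cohort, qc_report=report,
                          gwas=gwas, candidates=candidates, search=search,
                          prs_scores=prs_scores, prs_categories=prs_cats,
                          interactions=interactions)
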