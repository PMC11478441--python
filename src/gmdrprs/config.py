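"""Pipeline configuration: a validated YAML schema with safe defaults.

Unknown keys are rejected so typos fail loudly before any stage runs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .qc import QCThresholds

__all__ = ["PipelineConfig", "load_config", "config_hash"]

_TOP_KEYS = {
    "seed", "n_samples", "snps", "effect_model", "exposures",
    "qc", "gwas_alpha", "covariate_set", "ld_threshold",
    "gmdr", "prs", "strata", "dii_scores_path", "paths",
}
_GMDR_KEYS = {"k_range", "n_folds", "threshold", "budget"}
_PRS_KEYS = {"cut_points", "missing_policy"}


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, with field-standard defaults."""

    seed: int = 0
    n_samples: int = 5000
    snps: list = field(default_factory=list)          # list of SNPSpec kwargs dicts
    effect_model: dict = field(default_factory=dict)  # EffectModel kwargs
    exposures: dict | None = None                     # None -> default config
    qc: QCThresholds = field(default_factory=QCThresholds)
    gwas_alpha: float = 5e-4
    covariate_set: str = "covariate_set_2"
    ld_threshold: float = 0.4
    k_range: tuple = (1, 2, 3)
    n_folds: int = 10
    gmdr_threshold: float = 0.0
    budget: int = 20000
    prs_cut_points: object = (6, 8)
    prs_missing_policy: str = "exclude"
    strata: list = field(default_factory=lambda: ["wbc", "smoking", "coffee"])
    dii_scores_path: str | None = None
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        return d


def load_config(path_or_dict) -> PipelineConfig:
    """Load and validate a YAML config file (or an equivalent dict)."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    for key in ("seed", "n_samples", "snps", "effect_model", "exposures",
                "gwas_alpha", "covariate_set", "ld_threshold", "strata",
                "dii_scores_path", "paths"):
        if key in raw:
            kwargs[key] = raw[key]
    if "qc" in raw:
        bad = set(raw["qc"]) - {"max_missing", "min_maf", "min_hwe_p", "max_het"}
        if bad:
            raise ConfigError(f"unknown qc keys: {sorted(bad)}")
        kwargs["qc"] = QCThresholds(**raw["qc"])
    if "gmdr" in raw:
        bad = set(raw["gmdr"]) - _GMDR_KEYS
        if bad:
            raise ConfigError(f"unknown gmdr keys: {sorted(bad)}")
        g = raw["gmdr"]
        if "k_range" in g:
            kwargs["k_range"] = tuple(g["k_range"])
        if "n_folds" in g:
            kwargs["n_folds"] = int(g["n_folds"])
        if "threshold" in g:
            kwargs["gmdr_threshold"] = float(g["threshold"])
        if "budget" in g:
            kwargs["budget"] = int(g["budget"])
    if "prs" in raw:
        bad = set(raw["prs"]) - _PRS_KEYS
        if bad:
            raise ConfigError(f"unknown prs keys: {sorted(bad)}")
        p = raw["prs"]
        if "cut_points" in p:
            cp = p["cut_points"]
            kwargs["prs_cut_points"] = cp if isinstance(cp, str) else tuple(cp)
        if "missing_policy" in p:
            kwargs["prs_missing_policy"] = p["missing_policy"]
    try:
        return PipelineConfig(**kwargs)
    except TypeError as e:  # pragma: no cover - guarded by key checks above
        raise ConfigError(str(e)) from e


def config_hash(config: PipelineConfig) -> str:
    """Stable SHA-256 fingerprint of the full configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()
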