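"""Core in-memory containers shared across pipeline stages.

Genotypes are held as a dense sample x SNP matrix of minor-allele dosages
(0, 1, 2) with ``numpy.nan`` marking missing calls, alongside a per-SNP
metadata frame (chromosome, position, allele labels).  A cohort bundles the
genotype matrix with a per-sample phenotype/covariate/exposure table and,
for simulated data, a record of the effects that were planted.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError

SNP_META_COLUMNS = ["chrom", "pos", "minor_allele", "major_allele"]


@dataclass
class GenotypeMatrix:
    """Sample x SNP minor-allele dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` float array of minor-allele counts; ``nan``
        marks a missing call.
    snp_ids, sample_ids
        Column and row labels, in matrix order.
    snps
        Per-SNP metadata indexed by SNP id with columns ``chrom``, ``pos``,
        ``minor_allele``, ``major_allele``.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = list(self.snp_ids)
        self.sample_ids = list(self.sample_ids)
        if self.dosages.ndim != 2:
            raise ParameterError("dosages must be a 2-D sample x SNP array")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ParameterError(
                f"shape mismatch: dosages {self.dosages.shape} vs "
                f"{len(self.sample_ids)} samples / {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != m:
            raise ParameterError("duplicate SNP ids")
        self.snps = self.snps.reindex(self.snp_ids)
        for col in SNP_META_COLUMNS:
            if col not in self.snps.columns:
                raise ParameterError(f"snps metadata missing column {col!r}")
        with np.errstate(invalid="ignore"):
            bad = np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2
        if bad:
            raise ParameterError("dosages must lie in {0, 1, 2} or be nan")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector for one SNP (a copy)."""
        j = self.snp_ids.index(snp_id)
        return self.dosages[:, j].copy()

    def subset(self, snp_ids=None, sample_idx=None) -> "GenotypeMatrix":
        """Sub-matrix restricted to the given SNPs and/or sample row indices."""
        snp_ids = list(snp_ids) if snp_ids is not None else self.snp_ids
        cols = [self.snp_ids.index(s) for s in snp_ids]
        d = self.dosages[:, cols]
        samples = self.sample_ids
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.sample_ids[i] for i in sample_idx]
        return GenotypeMatrix(d.copy(), snp_ids, samples, self.snps.loc[snp_ids].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


def default_snp_meta(snp_ids, chrom="1", start_pos=1000, spacing=1000,
                     minor_allele="A", major_allele="G") -> pd.DataFrame:
    """Convenience metadata frame for simulated SNPs (evenly spaced loci)."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": [start_pos + i * spacing for i in range(len(snp_ids))],
            "minor_allele": minor_allele,
            "major_allele": major_allele,
        },
        index=list(snp_ids),
    )


@dataclass
class TruthRecord:
    """What was planted into a simulated cohort, for downstream validation."""

    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    risk_alleles: dict[str, str] = field(default_factory=dict)
    true_or_high_vs_low_prs: float | None = None
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["planted_pairs"] = [list(p) for p in self.planted_pairs]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["planted_pairs"] = [tuple(p) for p in d.get("planted_pairs", [])]
        return cls(**d)


@dataclass
class CohortDataset:
    """Genotypes + per-sample table (outcome, covariates, exposures) + truth.

    The table must carry a binary ``outcome`` column with at least one case
    and one control, and its rows must align with the genotype matrix.
    """

    genotypes: GenotypeMatrix
    table: pd.DataFrame
    truth: TruthRecord | None = None

    def __post_init__(self):
        if len(self.table) != self.genotypes.n_samples:
            raise ParameterError("table rows do not match genotype samples")
        if "outcome" not in self.table.columns:
            raise ParameterError("table must contain an 'outcome' column")
        y = self.table["outcome"].to_numpy()
        if not np.isin(y, [0, 1]).all():
            raise ParameterError("outcome must be binary 0/1")
        if y.sum() == 0 or y.sum() == len(y):
            raise ParameterError("cohort needs at least one case and one control")

    @property
    def outcome(self) -> np.ndarray:
        return self.table["outcome"].to_numpy(dtype=int)
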