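"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as a biallelic VCF (GT field, 1-based positions)
or as a dosage TSV (rows = samples, header = SNP ids, values = minor-allele
counts 0/1/2 with ``NA`` for missing).  Phenotype/exposure tables are TSV
with a header; truth records are JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, TruthRecord, default_snp_meta
from .errors import ParameterError

__all__ = [
    "read_genotypes", "read_dosage_tsv", "write_dosage_tsv",
    "read_vcf", "write_vcf", "read_phenotypes", "write_phenotypes",
    "read_truth", "write_truth",
]


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Dosage TSV: first column ``sample_id``, then one column per SNP id;
    values are minor-allele counts, ``NA`` for missing calls."""
    df = genotypes.to_dataframe()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_dosage_tsv(path, snps_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    vals = df.to_numpy(dtype=float)
    ids = list(df.columns)
    meta = snps_meta if snps_meta is not None else default_snp_meta(ids)
    return GenotypeMatrix(vals, ids, [str(s) for s in df.index], meta)


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal biallelic VCFv4.2 with a GT field.

    REF is the major allele, ALT the minor allele, so the ALT-allele count
    equals the stored minor-allele dosage.
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for chrom in dict.fromkeys(genotypes.snps["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT", *genotypes.sample_ids]
    lines.append("\t".join(header))
    for j, snp in enumerate(genotypes.snp_ids):
        meta = genotypes.snps.loc[snp]
        gts = [("./." if np.isnan(v) else _GT_CODE[v]) for v in genotypes.dosages[:, j]]
        lines.append("\t".join([str(meta["chrom"]), str(int(meta["pos"])), snp,
                                str(meta["major_allele"]), str(meta["minor_allele"]),
                                ".", "PASS", ".", "GT", *gts]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a minor-allele dosage matrix (via cyvcf2).

    The ALT-allele count is folded onto the minor allele: if ALT frequency
    exceeds 0.5 among called genotypes, dosage becomes ``2 - alt_count``
    and the allele labels swap.  Multi-allelic records are rejected with
    their position reported.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, meta_rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParameterError(
                f"multi-allelic record at {var.CHROM}:{var.POS} not supported")
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.array(var.gt_types, dtype=float)
        alt = np.where(codes == 2, np.nan, np.where(codes == 3, 2.0, codes))
        called = alt[~np.isnan(alt)]
        ref, altallele = var.REF, var.ALT[0]
        if called.size and called.mean() / 2.0 > 0.5:
            alt = 2.0 - alt
            minor, major = ref, altallele
        else:
            minor, major = altallele, ref
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(alt)
        meta_rows.append({"chrom": var.CHROM, "pos": var.POS,
                          "minor_allele": minor, "major_allele": major})
    meta = pd.DataFrame(meta_rows, index=ids)
    return GenotypeMatrix(np.column_stack(rows) if rows else np.empty((len(samples), 0)),
                          ids, samples, meta)


def read_genotypes(path, fmt: str | None = None,
                   sample_ids=None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' | 'dosage'), inferring from the suffix.

    If ``sample_ids`` (e.g. from the phenotype table) is given, a mismatch
    with the genotype samples raises, listing the offenders.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "dosage"
    gm = read_vcf(path) if fmt == "vcf" else read_dosage_tsv(path)
    if sample_ids is not None:
        expected = set(sample_ids)
        got = set(gm.sample_ids)
        if expected != got:
            offenders = sorted(expected ^ got)[:10]
            raise ParameterError(
                f"sample-id mismatch between genotypes and phenotypes; "
                f"first offenders: {offenders}")
    return gm


def write_phenotypes(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_truth(truth: TruthRecord, path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path) -> TruthRecord:
    return TruthRecord.from_json(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
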