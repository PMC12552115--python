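"""Readers and writers for the pipeline's tab-separated and VCF formats.

Conventions: all tables are TSV with "NA" as the sole absence token;
metadata (package version, seed, weight configuration, ...) is written as
``## key=value`` comment lines before the header and ignored on read.
Genotypes may come as VCF (GT fields, 1-based positions; multi-allelic
records are split into bi-allelic rows) or as a TSV matrix with one row per
individual and one column per variant.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MISSING_DOSAGE, GenePhenotypePair, GenotypeMatrix, validate_cohort

__all__ = [
    "read_table",
    "write_table",
    "read_variants",
    "write_variants",
    "read_cohort",
    "write_cohort",
    "read_gene_pairs",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
]

NA = "NA"


def _metadata_lines(metadata: dict | None) -> list[str]:
    if not metadata:
        return []
    return [f"## {k}={v}" for k, v in metadata.items()]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                index: bool = False) -> None:
    """Write a TSV with optional ``## key=value`` metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _metadata_lines(metadata):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", na_rep=NA, index=index)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV, returning (table, metadata dict from ## lines)."""
    metadata = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("##"):
            body_start = i + 1
            kv = line[2:].strip()
            if "=" in kv:
                k, v = kv.split("=", 1)
                metadata[k.strip()] = v.strip()
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                     na_values=[NA], keep_default_na=False)
    return df, metadata


def write_variants(variants: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_table(variants, path, metadata)


def read_variants(path) -> pd.DataFrame:
    """Annotation table: variant_id, gene, consequence, maf, then score columns."""
    df, meta = read_table(path)
    required = ["variant_id", "gene", "consequence", "maf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variants table missing columns {missing}")
    df.attrs["metadata"] = meta
    return df


def write_cohort(cohort: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_table(cohort, path, metadata)


def read_cohort(path) -> pd.DataFrame:
    df, meta = read_table(path)
    validate_cohort(df)
    df.attrs["metadata"] = meta
    return df


def read_gene_pairs(path) -> list[GenePhenotypePair]:
    """Gene-phenotype pair list: columns gene, phenotype, direction."""
    df, _ = read_table(path)
    required = ["gene", "phenotype", "direction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pair list missing columns {missing}")
    return [
        GenePhenotypePair(row.gene, row.phenotype, row.direction)
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_tsv(genotypes: GenotypeMatrix, path,
                        metadata: dict | None = None) -> None:
    df = genotypes.to_frame().astype(object)
    df[genotypes.dosages == MISSING_DOSAGE] = np.nan
    write_table(df.reset_index(), path, metadata)


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    df, _ = read_table(path)
    if df.columns[0] != "individual_id":
        raise ValueError(f"{path}: first column must be individual_id")
    ids = df["individual_id"].astype(str).tolist()
    dupes = df["individual_id"][df["individual_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate individual_ids {dupes}")
    body = df.drop(columns=["individual_id"])
    arr = body.to_numpy(dtype=float)
    bad = ~(np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0)))
    if bad.any():
        rows = (np.where(bad.any(axis=1))[0] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: invalid dosage cells on lines {rows}")
    arr = np.where(np.isnan(arr), MISSING_DOSAGE, arr).astype(np.int8)
    return GenotypeMatrix(arr, ids, list(body.columns))


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicate sample ids in VCF header")
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        geno = np.array([g[:2] for g in rec.genotypes], dtype=int)
        for k, alt in enumerate(rec.ALT, start=1):
            vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            dosage = (geno == k).sum(axis=1).astype(np.int8)
            dosage[(geno < 0).any(axis=1)] = MISSING_DOSAGE
            variant_ids.append(vid)
            columns.append(dosage)
    if not columns:
        raise ValueError(f"{path}: VCF contains no variant records")
    dupes = pd.Series(variant_ids)
    dupes = dupes[dupes.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate variant ids after splitting: {dupes}")
    return GenotypeMatrix(np.column_stack(columns), samples, variant_ids)


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV.

    ``format`` is "vcf" or "tsv"; by default it is inferred from the file
    extension (.vcf / .vcf.gz -> VCF, otherwise TSV).
    """
    if format is None:
        name = str(path)
        format = "vcf" if name.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_DOSAGE: "./."}


def write_genotypes_vcf(genotypes: GenotypeMatrix, path,
                        metadata: dict | None = None) -> None:
    """Write a minimal VCF (GT only, 1-based positions from the variant ids).

    Every variant_id must be of the canonical ``chrom:pos:ref:alt`` form.
    """
    records = []
    for vid in genotypes.variant_ids:
        parts = vid.split(":")
        if len(parts) != 4:
            raise ValueError(f"variant_id {vid!r} is not chrom:pos:ref:alt")
        records.append(parts)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for k, v in (metadata or {}).items():
            fh.write(f"##{k}={v}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(genotypes.individual_ids) + "\n")
        for j, (chrom, pos, ref, alt) in enumerate(records):
            gts = "\t".join(_GT_BY_DOSAGE[int(d)] for d in genotypes.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t{chrom}:{pos}:{ref}:{alt}\t{ref}\t{alt}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
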