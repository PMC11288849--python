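"""Readers and writers for the genotype/phenotype file dialects.

Genotype CSV: comma-separated, UTF-8, header ``id,<marker1>,...`` with
optional ``family`` and ``population`` columns immediately after ``id``.
Missing genotype codes: the literal strings ``NA`` and ``""`` and the
value ``-9``. Phenotype CSV: ``id,progeny,population,year,plot,trait,value``.
VCF: v4.2+ biallelic SNPs, GT field; dosage = ALT-allele count.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PHENOTYPE_COLUMNS, GenotypeMatrix, PhenotypeRecords, _check_unique

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotype_csv",
    "write_genotype_csv",
    "read_genotype_vcf",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "VCFReadStats",
]

MISSING_CODES = {"NA", "", "-9", "-9.0"}


def read_genotype_csv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read an allele-dosage table; unparseable cells become missing."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"empty or header-only genotype file: {path}")
    first = df.columns[0]
    if first != "id":
        raise ValueError(f"genotype CSV must start with an 'id' column, got {first!r}")
    samples = df["id"].astype(str).tolist()
    _check_unique(samples, "sample")
    family = population = None
    cols = list(df.columns[1:])
    if cols and cols[0] == "family":
        family = df["family"].astype(str).tolist()
        cols = cols[1:]
    if cols and cols[0] == "population":
        population = df["population"].astype(str).tolist()
        cols = cols[1:]
    if not cols:
        raise ValueError(f"no marker columns in genotype file: {path}")
    _check_unique(cols, "marker")
    raw = df[cols].to_numpy(dtype=str)
    stripped = np.char.strip(raw)
    dosage = np.full(stripped.shape, np.nan)
    for codes, val in ((("0", "0.0"), 0.0), (("1", "1.0"), 1.0), (("2", "2.0"), 2.0)):
        dosage[np.isin(stripped, codes)] = val
    # anything else (declared missing codes or unparseable) stays nan
    known = ["0", "1", "2", "0.0", "1.0", "2.0"]
    unknown = ~np.isin(stripped, known) & ~np.isin(stripped, list(MISSING_CODES))
    if unknown.any():
        n_bad = int(unknown.sum())
        logger.warning("%d unparseable dosage cell(s) treated as missing", n_bad)
    return GenotypeMatrix(samples=samples, markers=cols, dosage=dosage,
                          family=family, population=population)


def write_genotype_csv(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    df = g.to_frame().reset_index()
    num_cols = g.markers
    out = df.copy()
    for c in num_cols:
        col = out[c].astype(float)
        if not g.continuous:
            s = col.map(lambda v: "NA" if not np.isfinite(v) else str(int(v)))
        else:
            s = col.map(lambda v: "NA" if not np.isfinite(v) else repr(float(v)))
        out[c] = s
    out.to_csv(path, index=False)


@dataclass
class VCFReadStats:
    records_read: int
    records_kept: int
    skipped_multiallelic: int
    skipped_non_snp: int


def read_genotype_vcf(path: str | os.PathLike, return_stats: bool = False):
    """Read biallelic SNP genotypes from a VCF into alt-dosage form.

    Multiallelic records are skipped with a logged warning and counted in the
    returned statistics; ``./.`` genotypes become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF has no sample columns: {path}")
    markers: list[str] = []
    rows: list[np.ndarray] = []
    n_read = n_multi = n_nonsnp = 0
    for rec in vcf:
        n_read += 1
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if not rec.is_snp:
            n_nonsnp += 1
            continue
        name = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        markers.append(name)
        # gts012: 0/1/2 = alt count, 3 = unknown
        gt = rec.gt_types.astype(float)
        gt[gt == 3] = np.nan
        rows.append(gt)
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multiallelic record(s)", n_multi)
    if not markers:
        raise ValueError(f"no biallelic SNP records in VCF: {path}")
    _check_unique(markers, "marker")
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    g = GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)
    if return_stats:
        return g, VCFReadStats(n_read, len(markers), n_multi, n_nonsnp)
    return g


def read_phenotype_csv(path: str | os.PathLike) -> PhenotypeRecords:
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype CSV {path} missing column(s): {missing}")
    for c in PHENOTYPE_COLUMNS[:-1]:
        df[c] = df[c].astype(str)
    df["value"] = df["value"].astype(float)
    return PhenotypeRecords(df)


def write_phenotype_csv(records: PhenotypeRecords, path: str | os.PathLike) -> None:
    records.table.to_csv(path, index=False)
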