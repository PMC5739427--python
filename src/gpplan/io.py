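"""Readers and writers for the field's standard exchange formats.

GRMs travel in the two GCTA dialects: the gzipped text triplet
(``prefix.grm.gz`` with 1-based lower-triangle rows ``i j n_snps value``
plus ``prefix.grm.id``) and the binary dialect (``prefix.grm.bin`` float32
lower triangle, ``prefix.grm.N.bin`` float32 pair-wise SNP counts,
``prefix.grm.id``).  Genotypes travel as PLINK1 binary (.bed/.bim/.fam,
SNP-major 2-bit codes), PLINK ``--recode A`` additive dosage tables
(.raw), or a plain two-file TSV format used for small fixtures.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .grm import GRM, MISSING, GenotypeMatrix

__all__ = [
    "write_grm_text",
    "read_grm_text",
    "write_grm_binary",
    "read_grm_binary",
    "read_grm",
    "read_plink_raw",
    "write_plink_bed",
    "read_plink_bed",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
]


# ---------------------------------------------------------------------------
# GCTA GRM dialects


def _write_grm_id(prefix: Path, ids: list[str]) -> None:
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")


def _read_grm_id(prefix: Path) -> list[str]:
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None, dtype=str)
    return ids.iloc[:, 1].tolist()


def write_grm_text(grm: GRM, prefix: str | Path) -> None:
    """Write the GCTA gzipped-text dialect: prefix.grm.gz + prefix.grm.id."""
    prefix = Path(prefix)
    n_snps = grm.n_snps or 1
    _write_grm_id(prefix, grm.individual_ids)
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for i in range(grm.n_individuals):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_snps}\t{grm.values[i, j]:.10g}\n")


def read_grm_text(prefix: str | Path) -> GRM:
    """Read the GCTA gzipped-text dialect (plain text also accepted)."""
    prefix = Path(prefix)
    ids = _read_grm_id(prefix)
    path = Path(f"{prefix}.grm.gz")
    if not path.exists():
        path = Path(f"{prefix}.grm")
    tbl = pd.read_csv(path, sep=r"\s+", header=None, names=["i", "j", "n", "value"], compression="infer")
    n = len(ids)
    values = np.zeros((n, n))
    ii = tbl["i"].to_numpy(dtype=int) - 1
    jj = tbl["j"].to_numpy(dtype=int) - 1
    values[ii, jj] = tbl["value"].to_numpy()
    values[jj, ii] = values[ii, jj]
    n_snps = int(tbl["n"].iloc[0]) if len(tbl) else None
    return GRM(individual_ids=ids, values=values, n_snps=n_snps)


def write_grm_binary(grm: GRM, prefix: str | Path) -> None:
    """Write the GCTA binary dialect: .grm.bin + .grm.N.bin + .grm.id."""
    prefix = Path(prefix)
    _write_grm_id(prefix, grm.individual_ids)
    n = grm.n_individuals
    tril = grm.values[np.tril_indices(n)]
    tril.astype("<f4").tofile(f"{prefix}.grm.bin")
    counts = np.full(tril.size, grm.n_snps or 1, dtype="<f4")
    counts.tofile(f"{prefix}.grm.N.bin")


def read_grm_binary(prefix: str | Path) -> GRM:
    """Read the GCTA binary dialect."""
    prefix = Path(prefix)
    ids = _read_grm_id(prefix)
    n = len(ids)
    tril = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    expected = n * (n + 1) // 2
    if tril.size != expected:
        raise ValueError(f"{prefix}.grm.bin holds {tril.size} values, expected {expected} for {n} ids")
    values = np.zeros((n, n))
    values[np.tril_indices(n)] = tril
    values = values + np.tril(values, -1).T
    n_path = Path(f"{prefix}.grm.N.bin")
    n_snps = int(np.fromfile(n_path, dtype="<f4")[0]) if n_path.exists() else None
    return GRM(individual_ids=ids, values=values, n_snps=n_snps)


def read_grm(prefix: str | Path) -> GRM:
    """Read a GRM, auto-detecting the GCTA text vs binary dialect."""
    if Path(f"{prefix}.grm.bin").exists():
        return read_grm_binary(prefix)
    return read_grm_text(prefix)


# ---------------------------------------------------------------------------
# PLINK .raw additive dosage table


def read_plink_raw(path: str | Path, chromosome_of_snp: Optional[np.ndarray] = None) -> GenotypeMatrix:
    """Read a PLINK ``--recode A`` dosage table (.raw).

    The six pedigree columns are dropped; NA becomes missing.  SNP column
    names keep any ``_allele`` suffix stripped.  A chromosome map may be
    supplied; otherwise all SNPs are placed on chromosome 1.
    """
    tbl = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in tbl.columns if c not in meta_cols]
    ids = tbl["IID"].astype(str).tolist()
    dose = tbl[snp_cols].to_numpy(dtype=float)
    d = np.where(np.isnan(dose), MISSING, dose).astype(np.int8)
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    chrom = chromosome_of_snp if chromosome_of_snp is not None else np.ones(len(snp_ids), dtype=np.int32)
    return GenotypeMatrix(individual_ids=ids, snp_ids=snp_ids, chromosome_of_snp=chrom, dosage=d)


# ---------------------------------------------------------------------------
# PLINK1 binary (.bed/.bim/.fam)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit code -> dosage of the A1 (counted) allele; 01 is missing.
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


def write_plink_bed(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PLINK1 .bed/.bim/.fam (SNP-major).

    The .bim cM field carries the genetic position in centimorgans
    (Morgans x 100) when the genotype matrix has one; alleles are written as
    A (counted) / B.
    """
    prefix = Path(prefix)
    n, m = genotypes.dosage.shape
    with open(f"{prefix}.fam", "w") as fh:
        for iid in genotypes.individual_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    pos = genotypes.genetic_position
    with open(f"{prefix}.bim", "w") as fh:
        for j, sid in enumerate(genotypes.snp_ids):
            cm = 0.0 if pos is None else 100.0 * pos[j]
            fh.write(f"{genotypes.chromosome_of_snp[j]}\t{sid}\t{cm:.6g}\t{j + 1}\tA\tB\n")
    # SNP-major packing: one SNP's genotypes per row, 4 individuals per byte.
    lut = np.empty(256, dtype=np.uint8)
    for dose, code in _DOSAGE_TO_BED_CODE.items():
        lut[dose & 0xFF] = code
    codes = lut[genotypes.dosage.T.astype(np.uint8)]  # m x n, values 0..3
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink_bed(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK1 .bed/.bim/.fam into a genotype matrix (A1 dosage)."""
    prefix = Path(prefix)
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
        dtype={"chrom": int, "snp": str, "cm": float, "bp": int, "a1": str, "a2": str},
    )
    ids = fam.iloc[:, 1].tolist()
    n, m = len(ids), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK1 .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    dosage = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    pos = bim["cm"].to_numpy() / 100.0
    return GenotypeMatrix(
        individual_ids=ids,
        snp_ids=bim["snp"].tolist(),
        chromosome_of_snp=bim["chrom"].to_numpy(dtype=np.int32),
        dosage=dosage,
        genetic_position=pos if np.any(pos != 0) else None,
    )


# ---------------------------------------------------------------------------
# Plain-text fixture format: prefix.geno.tsv (individuals x SNPs dosage
# table) + prefix.snps.tsv (snp, chromosome, position map).


def write_genotypes_tsv(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    geno = pd.DataFrame(
        genotypes.dosage, index=genotypes.individual_ids, columns=genotypes.snp_ids
    )
    geno.to_csv(f"{prefix}.geno.tsv", sep="\t", index_label="individual")
    snps = pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "chromosome": genotypes.chromosome_of_snp,
            "position_morgans": (
                genotypes.genetic_position
                if genotypes.genetic_position is not None
                else np.zeros(genotypes.n_snps)
            ),
        }
    )
    snps.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def read_genotypes_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    geno = pd.read_csv(f"{prefix}.geno.tsv", sep="\t", index_col=0)
    snps = pd.read_csv(f"{prefix}.snps.tsv", sep="\t")
    pos = snps["position_morgans"].to_numpy(dtype=float)
    return GenotypeMatrix(
        individual_ids=[str(i) for i in geno.index],
        snp_ids=[str(c) for c in geno.columns],
        chromosome_of_snp=snps["chromosome"].to_numpy(dtype=np.int32),
        dosage=geno.to_numpy(dtype=np.int8),
        genetic_position=pos if np.any(pos != 0) else None,
    )
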