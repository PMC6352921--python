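"""Readers and writers for the standard interchange formats.

PLINK 1.9 binary genotypes (.bed/.bim/.fam, SNP-major), a pedigree TSV with
a couple-ID column, phenotype TSVs, summary-statistics TSVs (with automatic
OR -> log(OR) conversion), and the GCTA GRM binary dialect (float32 lower
triangle) plus a plain TSV GRM dialect.  All genomic coordinates are
1-based.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import PED_COLUMNS, Pedigree
from .relmat import RelationshipMatrix

_BED_MAGIC = b"\x6c\x1b\x01"  # PLINK v1.9 magic + SNP-major mode byte
# 2-bit code -> A1-allele dosage: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}


class PlinkFormatError(ValueError):
    pass


# ------------------------------------------------------------------- PLINK
def write_plink(prefix: str | Path, geno: GenotypeMatrix,
                ped: Pedigree | None = None) -> None:
    """Write .bed/.bim/.fam (SNP-major).  A1 is the effect allele."""
    prefix = Path(prefix)
    n, m = geno.n, geno.m
    if ped is not None and ped.ids != geno.ids:
        raise ValueError("pedigree and genotype individual order differ")
    fam = (ped.df[["fid", "iid", "father", "mother", "sex"]].copy()
           if ped is not None else
           pd.DataFrame({"fid": geno.ids, "iid": geno.ids, "father": "0",
                         "mother": "0", "sex": 0}))
    fam["pheno"] = -9
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = geno.snps.copy()
    bim.insert(2, "cm", 0)
    bim[["chrom", "snp", "cm", "bp", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    gt = geno.genotypes.T  # SNP-major
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[gt == dosage] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    packed[:, :n] = codes
    packed = packed.reshape(m, n_bytes, 4)
    byte = (packed[:, :, 0] | (packed[:, :, 1] << 2)
            | (packed[:, :, 2] << 4) | (packed[:, :, 3] << 6))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(byte.astype(np.uint8).tobytes())


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, Pedigree]:
    """Read .bed/.bim/.fam.  Dosages count the A1 allele (bim column 5)."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={0: str, 1: str, 2: str, 3: str})
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "bp", "a1", "a2"],
                      dtype={"snp": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes "
                               f"{raw[:3]!r} (expected PLINK v1.9 SNP-major)")
    n_bytes = (n + 3) // 4
    expected = 3 + n_bytes * m
    if len(raw) != expected:
        raise PlinkFormatError(f"{prefix}.bed: {len(raw)} bytes, expected "
                               f"{expected} for {n} individuals x {m} SNPs")
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = data & 0b11
    codes[:, 1::4] = (data >> 2) & 0b11
    codes[:, 2::4] = (data >> 4) & 0b11
    codes[:, 3::4] = (data >> 6) & 0b11
    geno = _CODE_TO_DOSAGE[codes[:, :n]].T
    snps = bim[["snp", "chrom", "bp", "a1", "a2"]].copy()
    ped_df = fam[["fid", "iid", "father", "mother", "sex"]].copy()
    ped_df["couple_id"] = "0"
    return (GenotypeMatrix(geno, fam["iid"].tolist(), snps),
            Pedigree(ped_df))


# ----------------------------------------------------------- pedigree / TSV
def write_pedigree(path: str | Path, ped: Pedigree) -> None:
    out = ped.df[PED_COLUMNS].copy()
    out.columns = ["FID", "IID", "PAT", "MAT", "SEX", "COUPLE_ID"]
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    ren = {"pat": "father", "mat": "mother"}
    df = df.rename(columns=ren)
    df["sex"] = df["sex"].astype(int)
    return Pedigree(df[PED_COLUMNS])


def write_phenotypes(path: str | Path, pheno: pd.DataFrame) -> None:
    out = pheno.rename(columns={"fid": "FID", "iid": "IID"})
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    return df.rename(columns={"FID": "fid", "IID": "iid"})


# ------------------------------------------------------------ summary stats
_SUMSTATS_RENAME = {"SNP": "snp", "CHR": "chrom", "BP": "bp", "A1": "a1",
                    "A2": "a2", "BETA": "beta", "OR": "or_", "SE": "se",
                    "P": "p", "N": "n"}


def write_sumstats(path: str | Path, stats_df: pd.DataFrame) -> None:
    out = stats_df.rename(columns={v: k for k, v in _SUMSTATS_RENAME.items()})
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV; an OR column is log-converted to beta."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    df = df.rename(columns=_SUMSTATS_RENAME)
    if "beta" not in df.columns:
        if "or_" not in df.columns:
            raise ValueError("summary statistics need a BETA or OR column")
        df["beta"] = np.log(df["or_"].astype(float))
    return df.drop(columns=[c for c in ("or_",) if c in df.columns])


# --------------------------------------------------------------- GCTA GRM
def write_grm_gcta(prefix: str | Path, grm: RelationshipMatrix,
                   n_snps: int | np.ndarray = 0) -> None:
    """GCTA binary dialect: float32 lower triangle (row-wise, diagonal
    included) in .grm.bin, per-pair SNP counts in .grm.N.bin, IDs in
    .grm.id."""
    prefix = str(prefix)
    n = grm.n
    il, jl = np.tril_indices(n)
    grm.values[il, jl].astype("<f4").tofile(prefix + ".grm.bin")
    counts = (np.broadcast_to(np.asarray(n_snps, float), (n, n))
              if np.ndim(n_snps) == 0 else np.asarray(n_snps, float))
    counts[il, jl].astype("<f4").tofile(prefix + ".grm.N.bin")
    pd.DataFrame({"fid": grm.ids, "iid": grm.ids}).to_csv(
        prefix + ".grm.id", sep="\t", header=False, index=False)


def read_grm_gcta(prefix: str | Path, component: str = "G"
                  ) -> tuple[RelationshipMatrix, np.ndarray]:
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None,
                      dtype=str)[1].tolist()
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(float)
    if len(tri) != n * (n + 1) // 2:
        raise ValueError(f"{prefix}.grm.bin length does not match {n} IDs")
    counts_tri = np.fromfile(prefix + ".grm.N.bin", dtype="<f4").astype(float)
    vals = np.zeros((n, n))
    counts = np.zeros((n, n))
    il, jl = np.tril_indices(n)
    vals[il, jl] = tri
    vals[jl, il] = tri
    counts[il, jl] = counts_tri
    counts[jl, il] = counts_tri
    return RelationshipMatrix(component, vals, ids), counts


def write_grm_tsv(path: str | Path, grm: RelationshipMatrix) -> None:
    """Plain TSV dialect: ID1, ID2, value for the lower triangle."""
    il, jl = np.tril_indices(grm.n)
    pd.DataFrame({"id1": [grm.ids[i] for i in il],
                  "id2": [grm.ids[j] for j in jl],
                  "value": grm.values[il, jl]}).to_csv(path, sep="\t", index=False)


def read_grm_tsv(path: str | Path, component: str = "G") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
    ids = list(dict.fromkeys(df["id1"]))
    pos = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    vals = np.zeros((n, n))
    for r in df.itertuples(index=False):
        i, j = pos[r.id1], pos[r.id2]
        vals[i, j] = vals[j, i] = r.value
    return RelationshipMatrix(component, vals, ids)
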