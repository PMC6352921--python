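"""In-memory genotype matrix (individuals x biallelic SNPs)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # int8 sentinel for a missing genotype call

SNP_COLUMNS = ["snp", "chrom", "bp", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes coded as counts of the A1 (effect) allele.

    Parameters
    ----------
    genotypes : ndarray, shape (n_individuals, n_snps), int8
        Values in {0, 1, 2} or ``MISSING`` (-1).
    ids : list of str
        Individual IDs, row order.
    snps : pandas.DataFrame
        Columns ``snp, chrom, bp, a1, a2`` (bp 1-based), column order.
    """

    genotypes: np.ndarray = field(repr=False)
    ids: list[str] = field(repr=False)
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.ids = [str(i) for i in self.ids]
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        if self.genotypes.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of IDs")
        if self.genotypes.shape[1] != len(self.snps):
            raise ValueError("column count does not match SNP table")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"SNP table missing columns: {missing_cols}")
        self.snps = self.snps.reset_index(drop=True).copy()
        if self.snps["snp"].duplicated().any():
            raise ValueError("duplicate SNP IDs")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def dosage(self, impute_mean: bool = False) -> np.ndarray:
        """Genotypes as float64 with missing as NaN (or mean-imputed per SNP)."""
        d = self.genotypes.astype(np.float64)
        d[self.genotypes == MISSING] = np.nan
        if impute_mean:
            mean = np.nanmean(d, axis=0)
            ix = np.where(np.isnan(d))
            d[ix] = mean[ix[1]]
        return d

    def allele_freq(self) -> np.ndarray:
        """Sample frequency of the A1 allele per SNP, ignoring missing calls."""
        d = self.dosage()
        return np.nanmean(d, axis=0) / 2.0

    def standardized(self) -> np.ndarray:
        """Per-SNP centred and variance-standardised dosages.

        Missing calls are mean-imputed (zero after centring); columns are
        scaled by sqrt(2 p (1-p)) with p the sample allele frequency.
        """
        p = self.allele_freq()
        if np.any((p <= 0) | (p >= 1)):
            bad = self.snps["snp"][(p <= 0) | (p >= 1)].tolist()
            raise ValueError(f"monomorphic SNPs cannot be standardised: {bad[:5]}")
        w = self.dosage(impute_mean=True) - 2.0 * p
        w /= np.sqrt(2.0 * p * (1.0 - p))
        return w

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        g = self.genotypes
        ids = self.ids
        snps = self.snps
        if rows is not None:
            rows = np.asarray(rows)
            g = g[rows]
            ids = [ids[i] for i in np.arange(len(self.ids))[rows]] if rows.dtype == bool else [ids[i] for i in rows]
        if cols is not None:
            cols = np.asarray(cols)
            g = g[:, cols]
            snps = snps.loc[np.arange(len(snps))[cols] if cols.dtype == bool else cols]
        return GenotypeMatrix(g.copy(), ids, snps.reset_index(drop=True))
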