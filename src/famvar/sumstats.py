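"""GWAS summary statistics and LD-score regression.

``mlma_loco`` produces per-SNP association statistics from individual-level
data with a mixed model whose GRM excludes the tested SNP's chromosome
(leave-one-chromosome-out, avoiding proximal contamination).  ``ld_scores``
computes windowed sums of adjusted r^2.  ``ldsc_h2`` and ``ldsc_rg`` regress
chi-square statistics (or cross-trait z-score products) on LD scores to
estimate SNP heritability and genetic correlation, with block-jackknife
standard errors.  ``z_diff`` compares two genetic correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .relmat import build_grm
from .vcomp import reml_fit


# ------------------------------------------------------------------- MLMA
def mlma_loco(y: np.ndarray, X: np.ndarray | None, geno: GenotypeMatrix
              ) -> pd.DataFrame:
    """Mixed-model association with a leave-one-chromosome-out GRM.

    For each chromosome c the variance components of y = Xb + g + e with
    g ~ N(0, sigma^2_g G_{-c}) are estimated by REML, then every SNP on c is
    tested as a fixed effect given those components (GLS score form).
    Returns a summary-statistics table (per-allele beta, se, p, n).
    """
    y = np.asarray(y, float).ravel()
    n = len(y)
    chroms = geno.snps["chrom"].unique()
    if len(chroms) < 2:
        raise ValueError("mlma_loco needs >= 2 chromosomes; use a plain-GRM "
                         "association for single-chromosome panels")
    Xc = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), np.asarray(X, float)])
    out = []
    for c in chroms:
        on = (geno.snps["chrom"] == c).to_numpy()
        grm = build_grm(geno.subset(cols=~on))
        fit = reml_fit(y, Xc, [grm])
        V = fit.variances["G"] * grm.values + fit.variances["resid"] * np.eye(n)
        Vi = np.linalg.inv(V)
        ViX = Vi @ Xc
        P = Vi - ViX @ np.linalg.solve(Xc.T @ ViX, ViX.T)
        W = geno.dosage(impute_mean=True)[:, on]
        W = W - W.mean(axis=0)
        PW = P @ W
        wPw = np.einsum("ij,ij->j", W, PW)
        wPy = PW.T @ y
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(wPw > 0, wPy / wPw, 0.0)
            se = np.where(wPw > 0, np.sqrt(1.0 / wPw), np.inf)
        z = beta / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        tab = geno.snps.loc[on, ["snp", "chrom", "bp", "a1", "a2"]].copy()
        tab["beta"], tab["se"], tab["p"], tab["n"] = beta, se, p, n
        out.append(tab)
    return pd.concat(out).sort_values(["chrom", "bp"]).reset_index(drop=True)


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic-control lambda: median chi2 over its null median."""
    chi2 = stats.chi2.isf(np.asarray(p, float), 1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


# --------------------------------------------------------------- LD scores
def ld_scores(reference: GenotypeMatrix, window_kb: float = 1000.0
              ) -> pd.DataFrame:
    """Per-SNP LD scores: l_j = 1 + sum over window of adjusted r^2.

    The small-sample adjustment r^2_adj = r^2 - (1 - r^2)/(n - 2) removes
    the expected upward bias of sample r^2 at linkage equilibrium.
    """
    w = reference.standardized()
    n = reference.n
    w = w / np.sqrt((w ** 2).mean(axis=0))  # exact unit variance per SNP
    snps = reference.snps
    l = np.ones(reference.m)
    window_bp = window_kb * 1000.0
    for _, grp in snps.groupby("chrom", sort=False):
        ix = grp.index.to_numpy()
        bp = grp["bp"].to_numpy(float)
        lo = 0
        for a, j in enumerate(ix):
            while bp[a] - bp[lo] > window_bp:
                lo += 1
            hi = a
            while hi + 1 < len(ix) and bp[hi + 1] - bp[a] <= window_bp:
                hi += 1
            others = np.r_[ix[lo:a], ix[a + 1:hi + 1]]
            if len(others) == 0:
                continue
            r2 = (w[:, j] @ w[:, others] / n) ** 2
            r2_adj = r2 - (1.0 - r2) / (n - 2)
            l[j] += float(r2_adj.sum())
    out = snps[["snp", "chrom", "bp"]].copy()
    out["ld_score"] = l
    return out


# -------------------------------------------------------------------- LDSC
def _jackknife_blocks(m: int, n_blocks: int) -> list[np.ndarray]:
    n_blocks = max(2, min(n_blocks, m))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
         skip: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (slope, intercept)."""
    if skip is not None:
        keep = np.ones(len(x), dtype=bool)
        keep[skip] = False
        x, y, w = x[keep], y[keep], w[keep]
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx ** 2
    if abs(det) < 1e-10 * max(sw * swxx, 1e-300):
        raise ValueError("regressor has no variation: LD scores (or sample "
                         "sizes) must vary across SNPs to separate slope "
                         "from intercept")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return float(slope), float(intercept)


def _ldsc_weights(l: np.ndarray, n: np.ndarray, m: int, h2: float) -> np.ndarray:
    lc = np.maximum(l, 1.0)
    return 1.0 / (lc * (1.0 + n * max(h2, 0.0) * lc / m) ** 2)


class H2Result(NamedTuple):
    h2: float
    se: float
    intercept: float


def ldsc_h2(stats_df: pd.DataFrame, ld: pd.DataFrame, n_blocks: int = 200
            ) -> H2Result:
    """SNP heritability by LD-score regression.

    chi2_j is regressed on n_j * l_j / m with a free intercept; the slope is
    h2.  Weights are 1/l heteroskedasticity weights sharpened once with the
    step-one h2 estimate; the SE is a contiguous-block jackknife.
    """
    df = stats_df.merge(ld[["snp", "ld_score"]], on="snp")
    m = len(df)
    if m < 20:
        raise ValueError("too few SNPs with LD scores for regression")
    z = (df["beta"] / df["se"]).to_numpy()
    chi2 = z ** 2
    l = df["ld_score"].to_numpy(float)
    n = df["n"].to_numpy(float)
    x = n * l / m
    w = _ldsc_weights(l, n, m, 0.0)
    h2_1, _ = _wls(x, chi2, w)
    w = _ldsc_weights(l, n, m, h2_1)
    h2, intercept = _wls(x, chi2, w)
    blocks = _jackknife_blocks(m, n_blocks)
    deleted = np.array([_wls(x, chi2, w, skip=b)[0] for b in blocks])
    nb = len(blocks)
    se = float(np.sqrt((nb - 1) / nb * np.sum((deleted - deleted.mean()) ** 2)))
    return H2Result(float(h2), se, float(intercept))


@dataclass
class GeneticCorrelationResult:
    """LDSC genetic correlation between two traits."""

    rG: float
    se: float
    h2_1: float
    h2_2: float
    gencov: float
    intercepts: tuple[float, float, float]  # trait1, trait2, cross-trait

    def z(self) -> float:
        return self.rG / self.se


def ldsc_rg(stats1: pd.DataFrame, stats2: pd.DataFrame, ld: pd.DataFrame,
            n_blocks: int = 200) -> GeneticCorrelationResult:
    """Cross-trait LD-score regression genetic correlation.

    z1j*z2j is regressed on sqrt(n1 n2) * l_j / m to give the genetic
    covariance slope; rG = gencov / sqrt(h2_1 h2_2).  The SE is a block
    jackknife of the full ratio (regression weights held at their full-data
    values).  Assumes non-overlapping cohorts (no shared-sample intercept
    term); the cross-trait intercept is left free.
    """
    df = stats1.merge(stats2, on="snp", suffixes=("_1", "_2")).merge(
        ld[["snp", "ld_score"]], on="snp")
    m = len(df)
    if m < 200:
        raise ValueError("fewer than 200 overlapping SNPs: genetic-correlation "
                         "regression is unidentifiable at this scale")
    z1 = (df["beta_1"] / df["se_1"]).to_numpy()
    z2 = (df["beta_2"] / df["se_2"]).to_numpy()
    l = df["ld_score"].to_numpy(float)
    n1 = df["n_1"].to_numpy(float)
    n2 = df["n_2"].to_numpy(float)

    x1, x2 = n1 * l / m, n2 * l / m
    xc = np.sqrt(n1 * n2) * l / m
    w1 = _ldsc_weights(l, n1, m, _wls(x1, z1 ** 2, _ldsc_weights(l, n1, m, 0.0))[0])
    w2 = _ldsc_weights(l, n2, m, _wls(x2, z2 ** 2, _ldsc_weights(l, n2, m, 0.0))[0])
    wc = np.sqrt(w1 * w2)

    def estimate(skip: np.ndarray | None):
        h2_1, i1 = _wls(x1, z1 ** 2, w1, skip)
        h2_2, i2 = _wls(x2, z2 ** 2, w2, skip)
        gencov, ic = _wls(xc, z1 * z2, wc, skip)
        denom = np.sqrt(max(h2_1, 1e-12) * max(h2_2, 1e-12))
        return gencov / denom, (h2_1, h2_2, gencov, i1, i2, ic)

    rg, (h2_1, h2_2, gencov, i1, i2, ic) = estimate(None)
    blocks = _jackknife_blocks(m, n_blocks)
    deleted = np.array([estimate(b)[0] for b in blocks])
    nb = len(blocks)
    se = float(np.sqrt((nb - 1) / nb * np.sum((deleted - deleted.mean()) ** 2)))
    if abs(rg) > 1.0:
        warnings.warn(f"genetic correlation estimate {rg:.3f} outside [-1, 1]",
                      stacklevel=2)
    rg = float(np.clip(rg, -1.25, 1.25))
    return GeneticCorrelationResult(rG=rg, se=se, h2_1=float(h2_1),
                                    h2_2=float(h2_2), gencov=float(gencov),
                                    intercepts=(float(i1), float(i2), float(ic)))


class ZDiffResult(NamedTuple):
    z: float
    p_one_sided: float
    p_two_sided: float


def z_diff(r1: float, se1: float, r2: float, se2: float) -> ZDiffResult:
    """Z-test for the difference of two (independent) correlation estimates.

    Z = (r1 - r2) / sqrt(se1^2 + se2^2).  Both the one-sided and the
    two-sided p are reported, since published comparisons mix conventions.
    """
    z = (r1 - r2) / np.sqrt(se1 ** 2 + se2 ** 2)
    return ZDiffResult(float(z), float(stats.norm.sf(abs(z))),
                       float(2.0 * stats.norm.sf(abs(z))))
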