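"""Polygenic risk scoring with LD clumping and mixed-model association.

The workflow mirrors the standard clumping-and-thresholding (C+T) approach:
discovery-GWAS summary statistics are LD-clumped against a genotype
reference (greedy by p-value, r^2 and window thresholds), scores are the
effect-size-weighted allele counts accumulated over a grid of p-value
inclusion thresholds, the best threshold is the one whose score explains
most trait variance on top of the covariates, and the association of that
score with a trait is tested in a linear mixed model with a pedigree random
effect to control for family structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .relmat import RelationshipMatrix
from .vcomp import LiabilityParams, liability_multiplier, reml_fit

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["snp", "chrom", "bp", "a1", "a2", "beta", "se", "p", "n"]
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

DEFAULT_THRESHOLDS = np.round(np.arange(1, 101) * 0.01, 2)


def validate_sumstats(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Check the summary-statistics contract (columns, p range, alleles)."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats_df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if stats_df["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids in summary statistics")
    p = stats_df["p"].to_numpy(float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (stats_df["a1"] == stats_df["a2"]).any():
        raise ValueError("effect and other allele must differ")
    return stats_df


@dataclass
class PRSProfile:
    """Per-individual scores across a p-value threshold grid."""

    ids: list[str] = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)  # (n_individuals, n_thresholds)
    n_snps: np.ndarray = field(repr=False)  # SNPs included at each threshold
    best_threshold: float | None = None
    best_r2: float | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.scores.shape != (len(self.ids), len(self.thresholds)):
            raise ValueError("scores shape mismatch")

    def at(self, threshold: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.thresholds - threshold)))
        return self.scores[:, j]


# -------------------------------------------------------------------- clump
def clump(stats_df: pd.DataFrame, reference: GenotypeMatrix,
          r2_max: float = 0.1, window_kb: float = 250.0) -> pd.DataFrame:
    """Greedy LD clumping of summary statistics against a genotype reference.

    The most significant unclaimed SNP becomes an index SNP; every unclaimed
    SNP on the same chromosome within ``window_kb`` kilobases and with
    genotypic r^2 above ``r2_max`` to it is removed.  Ties in p are broken
    by (chromosome, bp).  SNPs absent from the reference are dropped first.
    """
    stats_df = validate_sumstats(stats_df)
    ref_ix = {s: j for j, s in enumerate(reference.snps["snp"])}
    covered = stats_df["snp"].map(ref_ix).notna()
    if (~covered).any():
        logger.info("clump: dropping %d SNPs absent from the reference",
                    int((~covered).sum()))
    df = stats_df.loc[covered].copy()
    df["_ref"] = df["snp"].map(ref_ix).astype(int)
    df = df.sort_values(["p", "chrom", "bp"], kind="mergesort").reset_index(drop=True)

    dose = reference.dosage(impute_mean=True)
    window_bp = window_kb * 1000.0
    claimed = np.zeros(len(df), dtype=bool)
    keep_rows: list[int] = []
    chrom = df["chrom"].to_numpy()
    bp = df["bp"].to_numpy(float)
    for i in range(len(df)):
        if claimed[i]:
            continue
        keep_rows.append(i)
        claimed[i] = True
        near = (~claimed) & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_bp)
        cand = np.where(near)[0]
        if len(cand) == 0:
            continue
        x = dose[:, df["_ref"].iloc[i]]
        Y = dose[:, df["_ref"].iloc[cand].to_numpy()]
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=0)
        denom = np.sqrt((xc @ xc) * np.sum(Yc ** 2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, (xc @ Yc) ** 2 / denom ** 2, 0.0)
        claimed[cand[r2 > r2_max]] = True
    out = df.iloc[sorted(keep_rows)].drop(columns="_ref")
    return out.sort_values(["chrom", "bp"], kind="mergesort").reset_index(drop=True)


# -------------------------------------------------------------------- score
def _align(geno: GenotypeMatrix, stats_df: pd.DataFrame
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match summary stats to target SNPs; returns (target column indices,
    aligned effect sizes, p-values).  Effect sizes are flipped when the
    discovery effect allele is the target's other allele; strand-ambiguous
    and allele-mismatched SNPs are dropped."""
    tgt = geno.snps.set_index("snp")
    cols, betas, ps = [], [], []
    n_ambig = n_mismatch = 0
    col_of = {s: j for j, s in enumerate(geno.snps["snp"])}
    for row in stats_df.itertuples(index=False):
        if row.snp not in col_of:
            continue
        if frozenset((row.a1, row.a2)) in _AMBIGUOUS:
            n_ambig += 1
            continue
        t = tgt.loc[row.snp]
        if row.a1 == t.a1 and row.a2 == t.a2:
            sign = 1.0
        elif row.a1 == t.a2 and row.a2 == t.a1:
            sign = -1.0
        else:
            n_mismatch += 1
            continue
        cols.append(col_of[row.snp])
        betas.append(sign * row.beta)
        ps.append(row.p)
    if n_ambig or n_mismatch:
        logger.info("score: dropped %d strand-ambiguous and %d allele-mismatched SNPs",
                    n_ambig, n_mismatch)
    if not cols:
        raise ValueError("no SNPs overlap between summary statistics and target")
    return np.asarray(cols), np.asarray(betas), np.asarray(ps)


def score(geno: GenotypeMatrix, stats_df: pd.DataFrame,
          thresholds: np.ndarray | None = None) -> PRSProfile:
    """Cumulative weighted allele-count scores over a p-value threshold grid.

    ``score_i(t) = sum_{j: p_j <= t} beta_j * dosage_ij`` with missing
    dosages mean-imputed per SNP.  ``stats_df`` should already be clumped.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    stats_df = validate_sumstats(stats_df)
    cols, betas, ps = _align(geno, stats_df)
    dose = geno.dosage(impute_mean=True)[:, cols]
    # bin each SNP at the first threshold >= its p; cumulate bin scores
    bins = np.searchsorted(thresholds, ps - 1e-12, side="left")
    scores = np.zeros((geno.n, len(thresholds)))
    counts = np.zeros(len(thresholds), dtype=int)
    for b in np.unique(bins):
        if b >= len(thresholds):
            continue  # p above the last threshold: never included
        sel = bins == b
        scores[:, b] = dose[:, sel] @ betas[sel]
        counts[b] = int(sel.sum())
    return PRSProfile(ids=list(geno.ids), thresholds=thresholds,
                      scores=np.cumsum(scores, axis=1),
                      n_snps=np.cumsum(counts))


# --------------------------------------------------- mixed-model association
def _mixed_fixed_effects(y: np.ndarray, F: np.ndarray,
                         K: RelationshipMatrix | None):
    """Variance components for y ~ F + u (u ~ K) + e, then GLS for the fixed
    effects.  Returns (beta_hat, cov_beta, V_inverse, resid_df)."""
    if K is not None:
        fit = reml_fit(y, F, [K])
        V = fit.variances[K.component] * K.values + fit.variances["resid"] * np.eye(len(y))
    else:
        V = np.eye(len(y))
    Vi = np.linalg.inv(V)
    FtVi = F.T @ Vi
    cov = np.linalg.inv(FtVi @ F)
    beta = cov @ (FtVi @ y)
    if K is None:  # OLS: scale by residual variance estimate
        resid = y - F @ beta
        s2 = float(resid @ resid) / (len(y) - F.shape[1])
        cov = cov * s2
    return beta, cov, Vi, len(y) - F.shape[1]


def _varexp(F: np.ndarray, beta: np.ndarray) -> float:
    return float(np.var(F @ beta))


def prs_assoc(y: np.ndarray, prs: np.ndarray, X: np.ndarray | None,
              K: RelationshipMatrix | None,
              liability: LiabilityParams | None = None
              ) -> tuple[float, float, float, float]:
    """Association of a (standardised) PRS with a trait in a mixed model.

    Fits y = Xb + beta*PRS + u + e with u ~ N(0, sigma^2 K); returns
    (beta, se, incremental r^2, p) with p from Wald's conditional F-test
    (F(1, n-p)).  Incremental r^2 is the gain in fixed-effect explained
    variance over the covariate-only model, as a fraction of var(y).
    With ``liability`` given, beta and se are converted from the linear
    (observed) scale to the liability scale by the Taylor-series factor
    sqrt(c).
    """
    y = np.asarray(y, float).ravel()
    prs = np.asarray(prs, float).ravel()
    n = len(y)
    # X holds covariates without an intercept; one is prepended here
    Xc = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), np.asarray(X, float)])
    F = np.column_stack([Xc, prs])
    beta_cov, cov_cov, _, _ = _mixed_fixed_effects(y, Xc, K)
    beta_all, cov_all, _, df = _mixed_fixed_effects(y, F, K)
    b = float(beta_all[-1])
    se = float(np.sqrt(cov_all[-1, -1]))
    fstat = (b / se) ** 2
    p = float(stats.f.sf(fstat, 1, df))
    r2 = (_varexp(F, beta_all) - _varexp(Xc, beta_cov)) / float(np.var(y))
    if liability is not None:
        mult = np.sqrt(liability_multiplier(liability))
        b, se = b * mult, se * mult
    return b, se, float(r2), p


def liability_beta(beta: float, se: float, params: LiabilityParams
                   ) -> tuple[float, float]:
    """Linear-scale regression coefficient and SE to the liability scale
    (multiplication by sqrt of the variance-scale factor c)."""
    mult = np.sqrt(liability_multiplier(params))
    return beta * mult, se * mult


def best_threshold(profile: PRSProfile, y: np.ndarray,
                   X: np.ndarray | None, K: RelationshipMatrix | None
                   ) -> tuple[float, float]:
    """Pick the p-value threshold whose score explains most trait variance.

    For each threshold the incremental fixed-effect r^2 over the
    covariate-only mixed model (pedigree random effect) is computed with the
    variance components held at their covariate-only REML estimates; the
    argmax threshold is returned, ties going to the smallest threshold.
    Updates ``profile.best_threshold`` / ``best_r2`` in place.
    """
    y = np.asarray(y, float).ravel()
    n = len(y)
    Xc = np.ones((n, 1)) if X is None else np.column_stack([np.ones(n), np.asarray(X, float)])
    beta_cov, _, Vi, _ = _mixed_fixed_effects(y, Xc, K)
    base = _varexp(Xc, beta_cov)
    vary = float(np.var(y))
    r2s = np.empty(len(profile.thresholds))
    for j in range(len(profile.thresholds)):
        s = profile.scores[:, j]
        sd = s.std()
        if sd == 0:
            r2s[j] = 0.0
            continue
        F = np.column_stack([Xc, (s - s.mean()) / sd])
        FtVi = F.T @ Vi
        beta = np.linalg.solve(FtVi @ F, FtVi @ y)
        r2s[j] = (_varexp(F, beta) - base) / vary
    best = int(np.argmax(r2s))  # argmax returns the first (smallest) on ties
    profile.best_threshold = float(profile.thresholds[best])
    profile.best_r2 = float(r2s[best])
    return profile.best_threshold, profile.best_r2


def bonferroni(alpha: float, n_tests: int) -> float:
    """Multiple-testing-corrected per-test significance threshold."""
    return alpha / n_tests
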