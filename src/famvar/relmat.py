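"""Covariance structures for the family variance model, plus genotype QC.

Five symmetric N x N matrices drive the linear mixed model:

* G — genomic relationship matrix from genome-wide SNPs (GRM); its variance
  component is the SNP heritability.
* K — pedigree numerator relationship matrix (2x kinship), capturing
  additive genetic variance not tagged by the SNPs.
* F / C / S — {0,1} block indicator matrices with unit diagonal for
  environment shared by nuclear-family members, spouse couples and full
  siblings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree, PedigreeError

COMPONENTS = ("G", "K", "F", "C", "S")


@dataclass
class RelationshipMatrix:
    """A labelled symmetric covariance structure over ordered individuals."""

    component: str
    values: np.ndarray = field(repr=False)
    ids: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ID count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)  # exact symmetry

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_nonzero_offdiag(self) -> int:
        off = self.values - np.diag(np.diag(self.values))
        return int(np.count_nonzero(off))

    def bend(self, eps: float = 1e-6) -> "RelationshipMatrix":
        """Return a copy with ``eps`` added to the diagonal (used only when a
        singular F/C/S matrix must be inverted)."""
        return RelationshipMatrix(self.component,
                                  self.values + eps * np.eye(self.n), self.ids)

    def reorder(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {iid: i for i, iid in enumerate(self.ids)}
        ix = np.array([pos[i] for i in ids])
        return RelationshipMatrix(self.component,
                                  self.values[np.ix_(ix, ix)], list(ids))


# ------------------------------------------------------------------------ QC
@dataclass
class QCReport:
    """Counts of markers/individuals removed by each genotype QC filter."""

    individuals_removed_missing: int
    snps_removed_callrate: int
    snps_removed_maf: int
    snps_removed_hwe: int
    snps_remaining: int
    individuals_remaining: int


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact test of Hardy-Weinberg equilibrium.

    Conditions on observed allele counts and sums the probabilities of all
    heterozygote counts no more likely than the observed one (the standard
    exact SNP-HWE formulation).
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # probabilities over all feasible heterozygote counts (same parity)
    het_max = n_rare if n_rare <= n else 2 * n - n_rare
    hets = np.arange(n_rare % 2, het_max + 1, 2)
    logp = np.zeros(len(hets))
    # unnormalised log-probabilities via the hypergeometric-style recurrence
    mid = len(hets) // 2
    for i in range(mid, len(hets) - 1):
        h = hets[i]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[i + 1] = logp[i] + np.log(4.0 * hom_r * hom_c) - np.log((h + 2.0) * (h + 1.0))
    for i in range(mid, 0, -1):
        h = hets[i]
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[i - 1] = logp[i] + np.log(h * (h - 1.0)) - np.log(4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = np.searchsorted(hets, n_het)
    return float(min(1.0, prob[prob <= prob[obs] * (1 + 1e-12)].sum()))


def qc_genotypes(geno: GenotypeMatrix, callrate_min: float = 0.98,
                 indiv_missing_max: float = 0.02, maf_min: float = 0.01,
                 hwe_p_min: float = 1e-6) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard marker/sample QC filters, in a fixed order.

    Individuals with missingness >= ``indiv_missing_max`` are dropped first,
    then SNPs by call rate < ``callrate_min``, minor allele frequency <
    ``maf_min`` and exact-test HWE p <= ``hwe_p_min``.
    """
    miss = geno.missing_mask()
    indiv_keep = miss.mean(axis=1) < indiv_missing_max
    n_indiv_removed = int((~indiv_keep).sum())
    g = geno.subset(rows=indiv_keep) if n_indiv_removed else geno

    miss = g.missing_mask()
    callrate_keep = 1.0 - miss.mean(axis=0) >= callrate_min
    n_call = int((~callrate_keep).sum())
    g = g.subset(cols=callrate_keep)

    p = g.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    maf_keep = maf >= maf_min
    n_maf = int((~maf_keep).sum())
    g = g.subset(cols=maf_keep)

    hwe_keep = np.ones(g.m, dtype=bool)
    for j in range(g.m):
        col = g.genotypes[:, j]
        obs = col[col != MISSING]
        n_hom1 = int((obs == 0).sum())
        n_het = int((obs == 1).sum())
        n_hom2 = int((obs == 2).sum())
        if hwe_exact_test(n_het, n_hom1, n_hom2) <= hwe_p_min:
            hwe_keep[j] = False
    n_hwe = int((~hwe_keep).sum())
    g = g.subset(cols=hwe_keep)

    if g.m == 0:
        raise ValueError("all SNPs removed by QC filters")
    report = QCReport(individuals_removed_missing=n_indiv_removed,
                      snps_removed_callrate=n_call, snps_removed_maf=n_maf,
                      snps_removed_hwe=n_hwe, snps_remaining=g.m,
                      individuals_remaining=g.n)
    return g, report


# ----------------------------------------------------------------------- GRM
def build_grm(geno: GenotypeMatrix) -> RelationshipMatrix:
    """GREML genomic relationship matrix.

    A_jk = (1/m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    with p_i the sample allele frequency.  Missing genotypes are mean-imputed
    (zero contribution after centring) and the per-pair denominator m_jk
    counts only SNPs observed in both individuals.
    """
    p = geno.allele_freq()
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        bad = geno.snps["snp"][mono].tolist()
        raise ValueError(f"monomorphic SNPs in GRM input: {bad[:5]}")
    w = geno.standardized()
    miss = geno.missing_mask()
    if not miss.any():
        a = (w @ w.T) / geno.m
    else:
        obs = (~miss).astype(np.float64)
        pair_m = obs @ obs.T
        if (pair_m == 0).any():
            raise ValueError("individual pairs with no jointly observed SNPs")
        a = (w @ w.T) / pair_m
    return RelationshipMatrix("G", 0.5 * (a + a.T), geno.ids)


# ------------------------------------------------------------ pedigree (NRM)
def build_pedigree_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix (2x kinship) by the tabular method.

    Individuals are sorted parents-before-children internally; founders are
    taken unrelated and non-inbred.  Inbred pedigrees get diagonal
    1 + F via the standard recursion A_ii = 1 + A_fm / 2.
    """
    order = ped.topological_order()
    idx = ped.index_of()
    father = np.array([idx.get(f, -1) for f in ped.df["father"]])
    mother = np.array([idx.get(m, -1) for m in ped.df["mother"]])
    n = ped.n
    a = np.zeros((n, n))
    for i in order:
        f, m = father[i], mother[i]
        if f < 0:
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0 + 0.5 * a[f, m]
            row = 0.5 * (a[f, :] + a[m, :])
            row[i] = a[i, i]
            a[i, :] = row
            a[:, i] = row
    return RelationshipMatrix("K", a, ped.ids)


# -------------------------------------------------------- environment blocks
def _indicator(groups: list[list[str]], ids: list[str], label: str) -> RelationshipMatrix:
    pos = {iid: i for i, iid in enumerate(ids)}
    mat = np.eye(len(ids))
    for grp in groups:
        ix = np.array([pos[i] for i in grp])
        mat[np.ix_(ix, ix)] = 1.0
    return RelationshipMatrix(label, mat, ids)


def build_env_matrices(ped: Pedigree) -> tuple[RelationshipMatrix,
                                               RelationshipMatrix,
                                               RelationshipMatrix]:
    """Indicator covariance structures (F, C, S) with unit diagonals.

    C_jk = 1 iff j and k are spouses, S_jk = 1 iff full siblings, F_jk = 1
    iff members of the same nuclear family (a couple plus their children).
    """
    ids = ped.ids
    f = _indicator(ped.nuclear_families(), ids, "F")
    c = _indicator([list(pair) for pair in ped.couples()], ids, "C")
    s = _indicator(ped.sibships(), ids, "S")
    return f, c, s


def principal_components(grm: RelationshipMatrix, k: int = 4) -> np.ndarray:
    """Leading eigenvectors of the GRM, scaled by sqrt(eigenvalue).

    Used as fixed-effect covariates to absorb large-scale genetic structure
    (the desk-scale stand-in for reference-panel MDS components).
    """
    vals, vecs = np.linalg.eigh(grm.values)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))


def grm_vs_pedigree_correlation(grm: RelationshipMatrix,
                                nrm: RelationshipMatrix) -> float:
    """Pearson correlation of off-diagonal entries (diagnostic)."""
    if grm.ids != nrm.ids:
        nrm = nrm.reorder(grm.ids)
    iu = np.triu_indices(grm.n, k=1)
    return float(np.corrcoef(grm.values[iu], nrm.values[iu])[0, 1])
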