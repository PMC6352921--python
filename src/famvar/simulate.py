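"""Synthetic family cohorts with known variance-component ground truth.

The generators in this module produce the study design the estimators in the
rest of the package are meant for: nuclear families made of founder couples
and their full sibships, Mendelianly transmitted biallelic SNP genotypes
(with optional founder-haplotype LD), and phenotypes composed of SNP-genetic,
residual pedigree-genetic, nuclear-family, couple and sibling environment
components plus noise.  Binary traits are generated on the liability scale
and thresholded at the population prevalence, so liability-scale conversions
are exactly testable.

Everything is deterministic given the spec seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

# ordered allele pairs that are never strand-ambiguous
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


# --------------------------------------------------------------------- specs
@dataclass
class PedigreeSpec:
    """Design of a synthetic cohort: founder couples, sibships, singletons.

    ``n_children_dist`` maps sibship size (non-negative int) to probability.
    """

    n_couples: int
    n_children_dist: dict[int, float] = field(default_factory=lambda: {2: 1.0})
    n_singletons: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 0 or self.n_singletons < 0:
            raise ValueError("counts must be non-negative")
        sizes = list(self.n_children_dist)
        probs = np.array([self.n_children_dist[s] for s in sizes], float)
        if any((not float(s).is_integer()) or s < 0 for s in sizes):
            raise ValueError("sibship sizes must be non-negative integers")
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("sibship-size probabilities must be >=0 and sum to 1")


@dataclass
class GenomeSpec:
    """Marker panel layout: SNP count, MAF range, chromosomes, LD blocks.

    ``ld_block_size`` is the number of consecutive SNPs sharing founder
    haplotype correlation ``ld_rho`` (1 = linkage equilibrium); blocks never
    span chromosome boundaries.  Base-pair gaps between adjacent SNPs are
    uniform on [1, 2*mean_gap_bp), giving strictly increasing 1-based
    positions.
    """

    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_chromosomes: int = 1
    ld_block_size: int = 1
    ld_rho: float = 0.0
    mean_gap_bp: int = 5000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_chromosomes < 1 or self.n_snps < 1 or self.ld_block_size < 1:
            raise ValueError("counts must be positive")


@dataclass
class TraitSpec:
    """Generative variance fractions of a phenotype.

    var_G — additive effect of genotyped causal SNPs; var_K — residual
    pedigree-genetic effect (covariance proportional to the numerator
    relationship matrix); var_F / var_C / var_S — environment shared by
    nuclear family, couple and full sibs; the remainder is iid noise.
    """

    var_G: float = 0.0
    var_K: float = 0.0
    var_F: float = 0.0
    var_C: float = 0.0
    var_S: float = 0.0
    binary: bool = False
    prevalence: float = 0.5
    n_causal: int = 100
    seed: int = 0

    def fractions(self) -> dict[str, float]:
        return {"G": self.var_G, "K": self.var_K, "F": self.var_F,
                "C": self.var_C, "S": self.var_S}

    @property
    def var_resid(self) -> float:
        return 1.0 - sum(self.fractions().values())

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fractions().values()):
            raise ValueError("variance fractions must be non-negative")
        if self.var_resid < -1e-12:
            raise ValueError("variance fractions sum above 1")
        if self.binary and not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_causal < 1:
            raise ValueError("n_causal must be positive")


@dataclass
class TraitPairSpec:
    """Two traits with a configurable genetic correlation.

    ``rG`` is the correlation of causal-SNP effect sizes; ``causal_overlap``
    the fraction of causal SNPs shared between the traits (effects on shared
    SNPs are correlated rG / causal_overlap, so the genome-wide genetic
    correlation equals rG).
    """

    trait1: TraitSpec
    trait2: TraitSpec
    rG: float = 0.0
    causal_overlap: float = 1.0

    def __post_init__(self) -> None:
        if abs(self.rG) > 1:
            raise ValueError("|rG| must be <= 1")
        if not (0 < self.causal_overlap <= 1):
            raise ValueError("causal_overlap must be in (0, 1]")
        if abs(self.rG) > self.causal_overlap + 1e-12:
            raise ValueError("|rG| cannot exceed causal_overlap")


# ------------------------------------------------------------------ pedigree
def simulate_pedigree(spec: PedigreeSpec) -> Pedigree:
    """Generate a cohort of founder couples, their sibships and singletons.

    Children always have exactly two parents who form a couple; couples are
    founders (no remarriage or half-sibs).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = np.array(sorted(spec.n_children_dist), dtype=int)
    probs = np.array([spec.n_children_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    rows = []
    for f in range(spec.n_couples):
        fid = f"F{f + 1:05d}"
        dad, mum = f"{fid}_P1", f"{fid}_P2"
        cid = f"C{f + 1:05d}"
        rows.append((fid, dad, "0", "0", 1, cid))
        rows.append((fid, mum, "0", "0", 2, cid))
        k = int(rng.choice(sizes, p=probs))
        for c in range(k):
            rows.append((fid, f"{fid}_K{c + 1}", dad, mum,
                         int(rng.integers(1, 3)), "0"))
    for s in range(spec.n_singletons):
        fid = f"S{s + 1:05d}"
        rows.append((fid, f"{fid}_P1", "0", "0", int(rng.integers(1, 3)), "0"))
    df = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex",
                                     "couple_id"])
    return Pedigree(df)


# ----------------------------------------------------------------- genotypes
def _snp_table(genome: GenomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    m = genome.n_snps
    chrom_sizes = np.full(genome.n_chromosomes, m // genome.n_chromosomes)
    chrom_sizes[: m % genome.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, genome.n_chromosomes + 1), chrom_sizes)
    bp = np.empty(m, dtype=np.int64)
    start = 0
    for size in chrom_sizes:
        gaps = rng.integers(1, 2 * genome.mean_gap_bp, size=size)
        bp[start:start + size] = np.cumsum(gaps)
        start += size
    pair_ix = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    a1 = [_ALLELE_PAIRS[i][0] for i in pair_ix]
    a2 = [_ALLELE_PAIRS[i][1] for i in pair_ix]
    return pd.DataFrame({"snp": [f"rs{j + 1}" for j in range(m)],
                         "chrom": chroms.astype(int), "bp": bp,
                         "a1": a1, "a2": a2})


def _block_bounds(snps: pd.DataFrame, block_size: int) -> list[tuple[int, int]]:
    bounds = []
    for _, grp in snps.groupby("chrom", sort=True):
        lo, hi = grp.index[0], grp.index[-1] + 1
        for start in range(lo, hi, block_size):
            bounds.append((start, min(start + block_size, hi)))
    return bounds


def simulate_genotypes(ped: Pedigree, genome: GenomeSpec, seed: int = 0) -> GenotypeMatrix:
    """Draw founder haplotypes and transmit alleles Mendelianly.

    Founder haplotype alleles are Bernoulli(MAF) per SNP; within an LD block
    a Gaussian copula with exchangeable correlation ``ld_rho`` induces
    haplotype LD.  Each non-founder receives, independently per SNP, one of
    the two parental alleles from each parent.  The returned genotypes are
    counts of the A1 allele in {0, 1, 2}; no missingness is generated.
    """
    rng = np.random.default_rng(seed)
    snps = _snp_table(genome, rng)
    n, m = ped.n, genome.n_snps
    maf = rng.uniform(*genome.maf_range, size=m)
    thresh = stats.norm.ppf(maf)

    order = ped.topological_order()
    idx = ped.index_of()
    father = np.array([idx.get(f, -1) for f in ped.df["father"]])
    mother = np.array([idx.get(mo, -1) for mo in ped.df["mother"]])
    founders = np.where(father < 0)[0]

    hap = np.zeros((2, n, m), dtype=np.int8)
    blocks = _block_bounds(snps, genome.ld_block_size)
    rho = genome.ld_rho
    for h in range(2):
        z = rng.standard_normal((len(founders), m))
        if rho > 0 and genome.ld_block_size > 1:
            for lo, hi in blocks:
                shared = rng.standard_normal(len(founders))[:, None]
                z[:, lo:hi] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z[:, lo:hi]
        hap[h, founders] = (z < thresh).astype(np.int8)

    for i in order:
        if father[i] < 0:
            continue
        pick_f = rng.integers(0, 2, size=m)
        pick_m = rng.integers(0, 2, size=m)
        hap[0, i] = np.where(pick_f == 0, hap[0, father[i]], hap[1, father[i]])
        hap[1, i] = np.where(pick_m == 0, hap[0, mother[i]], hap[1, mother[i]])

    geno = (hap[0] + hap[1]).astype(np.int8)
    return GenotypeMatrix(geno, ped.ids, snps)


# ---------------------------------------------------------------- phenotypes
def _scale_to(x: np.ndarray, target_var: float) -> np.ndarray:
    """Centre ``x`` and rescale so its sample variance is exactly target_var."""
    if target_var == 0:
        return np.zeros_like(x)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot scale a constant component to positive variance")
    return x * (np.sqrt(target_var) / sd)


def _group_effects(groups: list[list[str]], ids: list[str],
                   rng: np.random.Generator) -> np.ndarray:
    """One N(0,1) draw per group, shared by its members; ungrouped
    individuals get their own independent draw (unit diagonal everywhere)."""
    pos = {iid: i for i, iid in enumerate(ids)}
    eff = rng.standard_normal(len(ids))
    for grp in groups:
        shared = rng.standard_normal()
        for iid in grp:
            eff[pos[iid]] = shared
    return eff


def _snp_genetic_values(geno: GenotypeMatrix, n_causal: int, var_G: float,
                        rng: np.random.Generator,
                        betas: np.ndarray | None = None,
                        causal: np.ndarray | None = None):
    p = geno.allele_freq()
    poly = np.where((p > 0) & (p < 1))[0]
    if causal is None:
        causal = rng.choice(poly, size=min(n_causal, len(poly)), replace=False)
        causal.sort()
    else:
        ok = np.isin(causal, poly)  # in-sample monomorphic SNPs drop out
        if betas is not None:
            betas = np.asarray(betas)[ok]
        causal = np.asarray(causal)[ok]
    if betas is None:
        betas = rng.standard_normal(len(causal))
    w = (geno.dosage(impute_mean=True)[:, causal] - 2.0 * p[causal])
    w /= np.sqrt(2.0 * p[causal] * (1.0 - p[causal]))
    g = w @ betas
    return _scale_to(g, var_G), causal, betas


def simulate_phenotypes(ped: Pedigree, geno: GenotypeMatrix | None,
                        trait: TraitSpec,
                        _g: np.ndarray | None = None) -> pd.DataFrame:
    """Compose a phenotype from genetic and shared-environment components.

    Each component is rescaled so its realised variance equals its spec'd
    fraction (parameter-recovery experiments then measure estimator error,
    not generator noise).  Returns a table with columns ``fid, iid, trait``
    and, for binary traits, the underlying ``liability``.
    """
    rng = np.random.default_rng(trait.seed)
    n = ped.n
    y = np.zeros(n)
    if _g is not None:
        y += _g
    elif trait.var_G > 0:
        if geno is None:
            raise ValueError("var_G > 0 requires genotypes")
        if geno.ids != ped.ids:
            raise ValueError("genotype and pedigree individual order differ")
        g, _, _ = _snp_genetic_values(geno, trait.n_causal, trait.var_G, rng)
        y += g
    if trait.var_K > 0:
        from .relmat import build_pedigree_matrix  # deferred: avoids cycle
        A = build_pedigree_matrix(ped).values
        L = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        y += _scale_to(L @ rng.standard_normal(n), trait.var_K)
    if trait.var_F > 0:
        y += _scale_to(_group_effects(ped.nuclear_families(), ped.ids, rng),
                       trait.var_F)
    if trait.var_C > 0:
        y += _scale_to(_group_effects([list(c) for c in ped.couples()],
                                      ped.ids, rng), trait.var_C)
    if trait.var_S > 0:
        y += _scale_to(_group_effects(ped.sibships(), ped.ids, rng),
                       trait.var_S)
    y += _scale_to(rng.standard_normal(n), trait.var_resid)

    out = ped.df[["fid", "iid"]].copy()
    if trait.binary:
        thr = stats.norm.ppf(1.0 - trait.prevalence)
        out["liability"] = y
        out["trait"] = (y > thr).astype(int)
    else:
        out["trait"] = y
    return out


def simulate_phenotype_pair(ped: Pedigree, geno: GenotypeMatrix,
                            spec: TraitPairSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two phenotypes whose causal-SNP effects have genetic correlation rG.

    A fraction ``causal_overlap`` of the causal SNPs is shared; on shared
    SNPs the two effect sizes are bivariate normal with correlation
    rG / causal_overlap, so the genome-wide correlation of genetic values is
    rG.  Non-genetic components are drawn independently per trait.
    """
    t1, t2 = spec.trait1, spec.trait2
    rng = np.random.default_rng(t1.seed)
    n_c = min(t1.n_causal, t2.n_causal, geno.m)
    n_shared = int(round(spec.causal_overlap * n_c))
    pool = rng.choice(geno.m, size=2 * n_c - n_shared, replace=False)
    shared, only1, only2 = (pool[:n_shared],
                            pool[n_shared:n_c],
                            pool[n_c:])
    rho = spec.rG / spec.causal_overlap
    z = rng.standard_normal((n_shared, 2))
    b_sh1 = z[:, 0]
    b_sh2 = rho * z[:, 0] + np.sqrt(max(0.0, 1 - rho ** 2)) * z[:, 1]

    causal1 = np.concatenate([shared, only1])
    causal2 = np.concatenate([shared, only2])
    beta1 = np.concatenate([b_sh1, rng.standard_normal(len(only1))])
    beta2 = np.concatenate([b_sh2, rng.standard_normal(len(only2))])

    tables = []
    for trait, causal, beta in ((t1, causal1, beta1), (t2, causal2, beta2)):
        sub_rng = np.random.default_rng(trait.seed + 1)
        g, _, _ = _snp_genetic_values(geno, len(causal), trait.var_G,
                                      sub_rng, betas=beta, causal=causal)
        tables.append(simulate_phenotypes(ped, geno, trait, _g=g))
    return tables[0], tables[1]


# ------------------------------------------------------------ summary stats
def simulate_sumstats(n: int, m: int, h2: float, rG: float = 0.0,
                      ld_scores: np.ndarray | None = None, seed: int = 0,
                      h2_2: float | None = None, n2: int | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a pair of GWAS summary-statistic tables from the LDSC model.

    Per SNP j with LD score l_j the z-scores satisfy
    E[z1j^2] = 1 + n1*h2_1*l_j/m,  E[z1j z2j] = rG*sqrt(h2_1 h2_2)*
    sqrt(n1 n2)*l_j/m (independent cohorts: no shared-sample intercept term).
    Effect sizes are beta = z/sqrt(n) in standardised-trait units.
    """
    h2_1 = h2
    h2_2 = h2 if h2_2 is None else h2_2
    n2 = n if n2 is None else n2
    for h in (h2_1, h2_2):
        if not (0 <= h <= 1):
            raise ValueError("h2 must be in [0, 1]")
    if abs(rG) > 1:
        raise ValueError("|rG| must be <= 1")
    rng = np.random.default_rng(seed)
    l = np.ones(m) if ld_scores is None else np.asarray(ld_scores, float)
    if len(l) != m:
        raise ValueError("ld_scores length must equal m")
    var1 = 1.0 + n * h2_1 * l / m
    var2 = 1.0 + n2 * h2_2 * l / m
    cov = rG * np.sqrt(h2_1 * h2_2) * np.sqrt(n * n2) * l / m
    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    z1 = np.sqrt(var1) * e1
    z2 = (cov / np.sqrt(var1)) * e1 + np.sqrt(np.maximum(var2 - cov ** 2 / var1, 0)) * e2

    def table(z: np.ndarray, n_: int) -> pd.DataFrame:
        se = np.full(m, 1.0 / np.sqrt(n_))
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        return pd.DataFrame({"snp": [f"rs{j + 1}" for j in range(m)],
                             "chrom": 1, "bp": (np.arange(m) + 1) * 1000,
                             "a1": "A", "a2": "G",
                             "beta": z * se, "se": se, "p": p, "n": n_})

    return table(z1, n), table(z2, n2)
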