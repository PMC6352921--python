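"""Clumping, scoring and mixed-model PRS association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famvar import (GenomeSpec, PedigreeSpec, TraitPairSpec, TraitSpec,
                    simulate_genotypes, simulate_pedigree,
                    simulate_phenotype_pair)
from famvar.genotypes import GenotypeMatrix
from famvar.prs import (best_threshold, bonferroni, clump, liability_beta,
                        prs_assoc, score)
from famvar.relmat import build_pedigree_matrix
from famvar.sumstats import mlma_loco
from famvar.vcomp import LiabilityParams

from test_relmat import make_geno


def make_stats(snps, betas, ps, chrom=1, bp=None, a1="A", a2="G", n=10000):
    m = len(snps)
    return pd.DataFrame({
        "snp": snps, "chrom": chrom,
        "bp": bp if bp is not None else (np.arange(m) + 1) * 1000,
        "a1": a1, "a2": a2, "beta": betas,
        "se": np.abs(np.asarray(betas)) / 2 + 0.01, "p": ps, "n": n})


def clump_oracle(stats_df, reference, r2_max, window_kb):
    """Exhaustive clumping with a precomputed full r^2 matrix."""
    d = reference.dosage(impute_mean=True)
    order = {s: j for j, s in enumerate(reference.snps["snp"])}
    r2 = np.corrcoef(d.T) ** 2
    df = stats_df.sort_values(["p", "chrom", "bp"], kind="mergesort")
    removed, kept = set(), []
    for row in df.itertuples(index=False):
        if row.snp in removed:
            continue
        kept.append(row.snp)
        for other in df.itertuples(index=False):
            if other.snp in removed or other.snp == row.snp or other.snp in kept:
                continue
            if (other.chrom == row.chrom
                    and abs(other.bp - row.bp) <= window_kb * 1000
                    and r2[order[row.snp], order[other.snp]] > r2_max):
                removed.add(other.snp)
    return sorted(kept)


class TestClump:
    def test_distant_snps_all_retained(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, (100, 5)).astype(np.int8)
        geno = make_geno(g, bp=np.arange(5) * 300_000 + 1)
        stats_df = make_stats([f"s{j}" for j in range(5)], np.ones(5),
                              [0.5, 0.1, 0.2, 0.3, 0.4],
                              bp=np.arange(5) * 300_000 + 1)
        out = clump(stats_df, geno)
        assert len(out) == 5

    def test_correlated_pair_keeps_most_significant(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 200).astype(np.int8)
        noise = rng.integers(0, 3, 200).astype(np.int8)
        y = np.where(rng.random(200) < 0.8, x, noise)  # r^2 well above 0.1
        geno = make_geno(np.column_stack([x, y]), bp=[1000, 11000])
        stats_df = make_stats(["s0", "s1"], [0.1, 0.1], [1e-4, 1e-8],
                              bp=[1000, 11000])
        out = clump(stats_df, geno)
        assert out["snp"].tolist() == ["s1"]  # the p=1e-8 SNP survives

    def test_matches_bruteforce_oracle(self):
        ped = simulate_pedigree(PedigreeSpec(0, {0: 1.0}, n_singletons=250,
                                             seed=2))
        geno = simulate_genotypes(ped, GenomeSpec(
            n_snps=100, ld_block_size=10, ld_rho=0.7, n_chromosomes=2,
            mean_gap_bp=40_000), seed=3)
        rng = np.random.default_rng(4)
        stats_df = geno.snps.copy()
        stats_df["beta"] = rng.standard_normal(100) * 0.05
        stats_df["se"] = 0.01
        stats_df["p"] = rng.uniform(1e-9, 1, 100)
        stats_df["n"] = 5000
        out = clump(stats_df, geno, r2_max=0.1, window_kb=250)
        assert sorted(out["snp"]) == clump_oracle(stats_df, geno, 0.1, 250)

    def test_uncovered_snps_dropped(self):
        geno = make_geno(np.zeros((10, 1), dtype=np.int8) + 1)
        stats_df = make_stats(["s0", "missing"], [0.1, 0.2], [0.5, 0.1],
                              bp=[1000, 2000])
        out = clump(stats_df, geno)
        assert out["snp"].tolist() == ["s0"]


class TestScore:
    def test_hand_worked_table(self):
        # 2 individuals x 3 SNPs with known dosages and weights
        geno = make_geno([[0, 1, 2], [2, 0, 1]])
        stats_df = make_stats(["s0", "s1", "s2"], [0.5, -1.0, 2.0],
                              [0.005, 0.25, 0.80])
        prof = score(geno, stats_df, thresholds=np.array([0.01, 0.5, 1.0]))
        # t=0.01: only s0; t=0.5: s0,s1; t=1: all three
        assert np.allclose(prof.scores[0], [0.0, -1.0, 3.0])
        assert np.allclose(prof.scores[1], [1.0, 1.0, 3.0])
        assert list(prof.n_snps) == [1, 2, 3]

    def test_zero_betas_zero_scores(self):
        geno = make_geno([[0, 1], [2, 1]])
        stats_df = make_stats(["s0", "s1"], [0.0, 0.0], [0.5, 0.5])
        prof = score(geno, stats_df)
        assert np.allclose(prof.scores, 0.0)

    def test_single_snp_unit_beta_counts_alleles(self):
        geno = make_geno([[0], [1], [2]])
        stats_df = make_stats(["s0"], [1.0], [0.5])
        prof = score(geno, stats_df)
        assert np.allclose(prof.scores[:, -1], [0, 1, 2])

    def test_allele_swap_flips_sign(self):
        geno = make_geno([[0], [1], [2]])
        swapped = make_stats(["s0"], [1.0], [0.5], a1="G", a2="A")
        prof = score(geno, swapped)
        # dosage of the discovery effect allele G is 2 - dosage(A)
        assert np.allclose(prof.scores[:, -1], [0, -1, -2])

    def test_ambiguous_snps_dropped(self):
        geno = make_geno([[1, 1], [2, 0]])
        stats_df = make_stats(["s0", "s1"], [1.0, 1.0], [0.5, 0.5], a1="A",
                              a2="G")
        stats_df.loc[0, ["a1", "a2"]] = ["A", "T"]  # strand-ambiguous
        prof = score(geno, stats_df)
        assert prof.n_snps[-1] == 1

    def test_no_overlap_is_error(self):
        geno = make_geno([[1], [1]])
        stats_df = make_stats(["other"], [1.0], [0.5])
        with pytest.raises(ValueError, match="no SNPs overlap"):
            score(geno, stats_df)

    def test_linearity_in_effect_sizes(self):
        rng = np.random.default_rng(5)
        geno = make_geno(rng.integers(0, 3, (20, 10)).astype(np.int8))
        ps = rng.uniform(0, 1, 10)
        b1, b2 = rng.standard_normal(10), rng.standard_normal(10)
        snps = [f"s{j}" for j in range(10)]
        s1 = score(geno, make_stats(snps, b1, ps)).scores
        s2 = score(geno, make_stats(snps, b2, ps)).scores
        s12 = score(geno, make_stats(snps, b1 + b2, ps)).scores
        assert np.allclose(s1 + s2, s12, atol=1e-10)

    def test_clumping_preserves_retained_weights(self):
        ped = simulate_pedigree(PedigreeSpec(0, {0: 1.0}, n_singletons=150,
                                             seed=6))
        geno = simulate_genotypes(ped, GenomeSpec(n_snps=60, ld_block_size=6,
                                                  ld_rho=0.8,
                                                  mean_gap_bp=2000), seed=7)
        rng = np.random.default_rng(8)
        stats_df = geno.snps.copy()
        stats_df["beta"] = rng.standard_normal(60) * 0.1
        stats_df["se"] = 0.01
        stats_df["p"] = rng.uniform(0, 1, 60)
        stats_df["n"] = 1000
        clumped = clump(stats_df, geno)
        full = score(geno, stats_df)
        reduced = score(geno, clumped)
        # rescoring the clumped subset from the full table matches exactly
        subset = score(geno, stats_df[stats_df["snp"].isin(clumped["snp"])])
        assert np.allclose(reduced.scores, subset.scores, atol=1e-12)
        assert not np.allclose(full.scores[:, -1], reduced.scores[:, -1])


class TestAssoc:
    def test_singleton_pedigree_reduces_to_ols(self):
        rng = np.random.default_rng(9)
        n = 200
        prs = rng.standard_normal(n)
        X = rng.standard_normal((n, 2))
        y = 0.3 * prs + X @ [0.2, -0.1] + rng.standard_normal(n)
        ped = simulate_pedigree(PedigreeSpec(0, {0: 1.0}, n_singletons=n))
        K = build_pedigree_matrix(ped)  # identity
        b_mm, se_mm, r2_mm, p_mm = prs_assoc(y, prs, X, K)
        b_ols, se_ols, r2_ols, p_ols = prs_assoc(y, prs, X, None)
        assert abs(b_mm - b_ols) < 1e-8
        assert abs(se_mm - se_ols) < 1e-5
        assert abs(p_mm - p_ols) < 1e-5

    def test_null_prs_type_one_error(self):
        rng = np.random.default_rng(10)
        n, hits = 150, 0
        for r in range(200):
            y = rng.standard_normal(n)
            prs = rng.standard_normal(n)
            _, _, _, p = prs_assoc(y, prs, None, None)
            hits += p < 0.05
        assert stats.binomtest(hits, 200, 0.05).pvalue > 0.01

    def test_genetically_correlated_discovery_transfers(self):
        """A PRS built from a discovery GWAS of a genetically correlated
        trait (rG=0.3) associates positively with the target trait."""
        genome = GenomeSpec(n_snps=800, n_chromosomes=4)
        disc_ped = simulate_pedigree(PedigreeSpec(0, {0: 1.0},
                                                  n_singletons=1200, seed=11))
        disc_geno = simulate_genotypes(disc_ped, genome, seed=12)
        tgt_ped = simulate_pedigree(PedigreeSpec(150, {2: 1.0}, seed=13))
        tgt_geno = simulate_genotypes(tgt_ped, genome, seed=14)

        pair = TraitPairSpec(trait1=TraitSpec(var_G=0.5, n_causal=200, seed=15),
                             trait2=TraitSpec(var_G=0.5, n_causal=200, seed=16),
                             rG=0.3)
        disc_y, _ = simulate_phenotype_pair(disc_ped, disc_geno, pair)
        _, tgt_y = simulate_phenotype_pair(tgt_ped, tgt_geno, pair)

        stats_df = mlma_loco(disc_y["trait"].to_numpy(), None, disc_geno)
        clumped = clump(stats_df, disc_geno)
        prof = score(tgt_geno, clumped)
        K = build_pedigree_matrix(tgt_ped)
        thr, r2 = best_threshold(prof, tgt_y["trait"].to_numpy(), None, K)
        s = prof.at(thr)
        b, se, r2i, p = prs_assoc(tgt_y["trait"].to_numpy(),
                                  (s - s.mean()) / s.std(), None, K)
        assert b > 0
        assert p < 0.05

    def test_best_threshold_is_argmax(self):
        rng = np.random.default_rng(17)
        geno = make_geno(rng.integers(0, 3, (120, 30)).astype(np.int8))
        stats_df = make_stats([f"s{j}" for j in range(30)],
                              rng.standard_normal(30) * 0.1,
                              rng.uniform(0, 1, 30))
        prof = score(geno, stats_df, thresholds=np.arange(0.1, 1.01, 0.1))
        y = rng.standard_normal(120)
        thr, best_r2 = best_threshold(prof, y, None, None)
        # recompute r2 for every threshold; none may beat the chosen one
        for j, t in enumerate(prof.thresholds):
            s = prof.scores[:, j]
            if s.std() == 0:
                continue
            _, _, r2, _ = prs_assoc(y, (s - s.mean()) / s.std(), None, None)
            assert r2 <= best_r2 + 1e-10


class TestLiabilityBeta:
    def test_zero_beta(self):
        assert liability_beta(0.0, 0.0, LiabilityParams(0.2, 0.3)) == (0.0, 0.0)

    def test_symmetric_point_sqrt_factor(self):
        b, se = liability_beta(1.0, 1.0, LiabilityParams(0.5, 0.5))
        assert np.isclose(b, np.sqrt(np.pi / 2), atol=1e-12)

    def test_round_trip(self):
        params = LiabilityParams(0.162, 0.164)
        b, se = liability_beta(0.21, 0.03, params)
        mult = b / 0.21
        assert abs(b / mult - 0.21) < 1e-12

    def test_bonferroni_guard(self):
        assert np.isclose(bonferroni(0.05, 18), 0.0028, atol=5e-5)
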