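"""Relationship matrices against hand values and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from famvar import (GenomeSpec, PedigreeSpec, Pedigree, simulate_genotypes,
                    simulate_pedigree)
from famvar.genotypes import MISSING, GenotypeMatrix
from famvar.pedigree import PedigreeError
from famvar.relmat import (build_env_matrices, build_grm,
                           build_pedigree_matrix, grm_vs_pedigree_correlation,
                           hwe_exact_test, qc_genotypes)


def make_geno(g, chrom=None, bp=None):
    g = np.asarray(g, dtype=np.int8)
    n, m = g.shape
    snps = pd.DataFrame({"snp": [f"s{j}" for j in range(m)],
                         "chrom": chrom if chrom is not None else 1,
                         "bp": bp if bp is not None else (np.arange(m) + 1) * 1000,
                         "a1": "A", "a2": "G"})
    return GenotypeMatrix(g, [f"i{i}" for i in range(n)], snps)


# ---------------------------------------------------------------------- GRM
class TestGRM:
    def test_single_snp_hand_values(self):
        # one SNP, p = 0.5: w = (x-1)/sqrt(0.5)
        geno = make_geno([[0], [1], [2]])
        grm = build_grm(geno)
        assert np.allclose(np.diag(grm.values), [2, 0, 2])
        assert np.isclose(grm.values[0, 2], -2)

    def test_unrelated_panel_expectation(self, singleton_cohort):
        _, geno = singleton_cohort
        grm = build_grm(geno)
        assert abs(np.mean(np.diag(grm.values)) - 1.0) < 0.02
        off = grm.values[np.triu_indices(grm.n, 1)]
        # centring on sample allele frequencies forces the off-diagonal mean
        # to -mean(diag)/(n-1); it should sit there, near zero
        assert np.isclose(off.mean(), -np.mean(np.diag(grm.values)) / (grm.n - 1),
                          atol=1e-10)
        assert abs(off.mean()) < 0.01

    def test_equals_bruteforce_oracle_with_missing(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(50, 200)).astype(np.int8)
        g[rng.random(g.shape) < 0.05] = MISSING
        geno = make_geno(g)
        grm = build_grm(geno)

        # independent double-loop evaluation of the estimator definition
        d = np.where(g == MISSING, np.nan, g).astype(float)
        p = np.nanmean(d, axis=0) / 2
        wc = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
        expect = np.empty((50, 50))
        for j in range(50):
            for k in range(50):
                both = ~np.isnan(wc[j]) & ~np.isnan(wc[k])
                expect[j, k] = np.sum(wc[j, both] * wc[k, both]) / both.sum()
        assert np.allclose(grm.values, expect, atol=1e-10)

    def test_monomorphic_snp_named_in_error(self):
        geno = make_geno([[1, 0], [1, 0], [1, 0]])
        with pytest.raises(ValueError, match="s1"):
            build_grm(geno)


# ------------------------------------------------------------- pedigree NRM
def kinship_oracle(ped: Pedigree):
    """Independent recursive-kinship implementation (memoised)."""
    parents = {r["iid"]: (r["father"], r["mother"])
               for _, r in ped.df.iterrows()}
    depth = {}

    def d(i):
        if i == "0":
            return -1
        if i not in depth:
            f, m = parents[i]
            depth[i] = 1 + max(d(f), d(m))
        return depth[i]

    memo = {}

    def phi(a, b):
        if a == "0" or b == "0":
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            f, m = parents[a]
            val = 0.5 * (1 + phi(f, m))
        else:
            if d(a) < d(b):
                a, b = b, a
            f, m = parents[a]
            val = 0.5 * (phi(f, b) + phi(m, b))
        memo[key] = val
        return val

    ids = ped.ids
    return np.array([[2 * phi(i, j) for j in ids] for i in ids])


class TestPedigreeMatrix:
    def test_textbook_relationships(self, three_generation_pedigree):
        ped = three_generation_pedigree
        K = build_pedigree_matrix(ped)
        ix = {iid: i for i, iid in enumerate(K.ids)}
        v = K.values
        assert v[ix["A"], ix["E"]] == 0.5          # parent-offspring
        assert v[ix["E"], ix["F"]] == 0.5          # full sibs
        assert v[ix["A"], ix["I"]] == 0.25         # grandparent-grandchild
        assert v[ix["F"], ix["I"]] == 0.25         # aunt-nephew
        assert v[ix["I"], ix["J"]] == 0.125        # first cousins
        assert v[ix["A"], ix["B"]] == 0.0          # founders unrelated

    def test_founder_matrix_identity(self):
        ped = simulate_pedigree(PedigreeSpec(0, {0: 1.0}, n_singletons=8))
        K = build_pedigree_matrix(ped)
        assert np.array_equal(K.values, np.eye(8))

    def test_equals_path_counting_oracle(self, three_generation_pedigree):
        K = build_pedigree_matrix(three_generation_pedigree)
        assert np.allclose(K.values, kinship_oracle(three_generation_pedigree),
                           atol=1e-12)

    def test_inbred_diagonal(self):
        # offspring of a parent-offspring mating: F = 0.25
        rows = [("f", "A", "0", "0", 1, "0"), ("f", "B", "0", "0", 2, "0"),
                ("f", "C", "A", "B", 2, "0"), ("f", "D", "A", "C", 1, "0")]
        ped = Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father",
                                                   "mother", "sex", "couple_id"]))
        K = build_pedigree_matrix(ped)
        assert np.isclose(K.values[3, 3], 1.25)

    def test_cycle_detected(self):
        rows = [("f", "A", "B", "C", 1, "0"), ("f", "B", "A", "C", 1, "0"),
                ("f", "C", "0", "0", 2, "0")]
        ped = Pedigree(pd.DataFrame(rows, columns=["fid", "iid", "father",
                                                   "mother", "sex", "couple_id"]))
        with pytest.raises(PedigreeError, match="cycle"):
            build_pedigree_matrix(ped)


# -------------------------------------------------------------- environment
class TestEnvMatrices:
    def test_four_person_family_enumeration(self):
        ped = simulate_pedigree(PedigreeSpec(1, {2: 1.0}))
        F, C, S = build_env_matrices(ped)
        assert C.n_nonzero_offdiag == 2 * 1     # one spouse pair
        assert S.n_nonzero_offdiag == 2 * 1     # one sib pair
        assert F.n_nonzero_offdiag == 2 * 6     # all 6 pairs of 4 members
        for m in (F, C, S):
            assert np.array_equal(np.diag(m.values), np.ones(4))

    def test_singletons_identity(self):
        ped = simulate_pedigree(PedigreeSpec(0, {0: 1.0}, n_singletons=6))
        for m in build_env_matrices(ped):
            assert np.array_equal(m.values, np.eye(6))

    def test_offdiag_counts_equal_twice_pairs(self, family_cohort):
        ped, _ = family_cohort
        F, C, S = build_env_matrices(ped)
        assert C.n_nonzero_offdiag == 2 * ped.n_couple_pairs()
        assert S.n_nonzero_offdiag == 2 * ped.n_fullsib_pairs()

    def test_support_nesting_and_psd(self, family_cohort):
        ped, geno = family_cohort
        F, C, S = build_env_matrices(ped)
        assert np.all(F.values[C.values > 0] > 0)  # couples inside family
        assert np.all(F.values[S.values > 0] > 0)  # sibs inside family
        K = build_pedigree_matrix(ped)
        G = build_grm(geno)
        for m in (F, C, S, K, G):
            assert np.allclose(m.values, m.values.T)
            assert np.linalg.eigvalsh(m.values).min() > -1e-8

    def test_individual_in_two_couples_rejected(self):
        rows = [("f", "A", "0", "0", 1, "c1"), ("f", "B", "0", "0", 2, "c1"),
                ("f", "Bx", "0", "0", 2, "c2"), ("f", "A2", "0", "0", 1, "c2")]
        df = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother",
                                         "sex", "couple_id"])
        df.loc[3, "iid"] = "A"  # A appears in c1 and c2
        with pytest.raises(PedigreeError):
            Pedigree(df)

    def test_grm_tracks_pedigree(self):
        ped = simulate_pedigree(PedigreeSpec(60, {2: 0.5, 3: 0.5}, seed=13))
        geno = simulate_genotypes(ped, GenomeSpec(n_snps=20000), seed=14)
        r = grm_vs_pedigree_correlation(build_grm(geno),
                                        build_pedigree_matrix(ped))
        assert r > 0.8


# ------------------------------------------------------------------------ QC
def hwe_oracle(n_het, n_hom1, n_hom2):
    """Exact HWE p by direct enumeration of the conditional distribution."""
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het

    def prob(h):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        if hr < 0 or hc < 0:
            return 0.0
        return (math.comb(n, hr) * math.comb(n - hr, h) * 2 ** h
                / math.comb(2 * n, n_rare))

    probs = {h: prob(h) for h in range(n_rare % 2, min(n_rare, n) + 1, 2)}
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


class TestQC:
    def test_hwe_exact_matches_enumeration(self):
        for trip in [(10, 45, 45), (50, 25, 25), (2, 40, 8), (21, 10, 30),
                     (0, 50, 50), (100, 0, 0)]:
            assert np.isclose(hwe_exact_test(*trip), hwe_oracle(*trip),
                              atol=1e-10)

    def test_clean_panel_untouched(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.25, size=(200, 30)).astype(np.int8)
        geno = make_geno(g)
        out, report = qc_genotypes(geno)
        assert report.snps_remaining == 30
        assert report.individuals_removed_missing == 0

    def test_low_maf_removed(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.25, size=(1000, 5)).astype(np.int8)
        g[:, 2] = 0
        g[:5, 2] = 1  # MAF 0.0025
        out, report = qc_genotypes(make_geno(g))
        assert report.snps_removed_maf == 1
        assert "s2" not in out.snps["snp"].tolist()

    def test_planted_violations_match_bruteforce(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, rng.uniform(0.05, 0.5, 100), size=(300, 100)).astype(np.int8)
        g[rng.random(g.shape) < 0.01] = MISSING
        g[:, 0][rng.random(300) < 0.2] = MISSING       # low call rate
        g[0, :][rng.random(100) < 0.5] = MISSING       # high indiv missing
        g[:, 1] = rng.binomial(2, 0.004, 300)          # low MAF
        g[:, 2] = 1                                    # all hets: HWE violation
        geno = make_geno(g)
        out, report = qc_genotypes(geno)

        # independent re-application of each rule, same order
        keep_i = (g == MISSING).mean(1) < 0.02
        h = g[keep_i]
        keep_call = (h == MISSING).mean(0) <= 0.02
        h2 = np.where(h == MISSING, np.nan, h).astype(float)
        p = np.nanmean(h2, 0) / 2
        keep_maf = np.minimum(p, 1 - p) >= 0.01
        keep = keep_call & keep_maf
        surviving = []
        for j in np.where(keep)[0]:
            col = h[:, j][h[:, j] != MISSING]
            pv = hwe_oracle(int((col == 1).sum()), int((col == 0).sum()),
                            int((col == 2).sum()))
            if pv > 1e-6:
                surviving.append(f"s{j}")
        assert out.snps["snp"].tolist() == surviving
        assert report.individuals_removed_missing == int((~keep_i).sum())

    def test_all_removed_is_error(self):
        g = np.ones((100, 2), dtype=np.int8)  # all-het SNPs fail HWE
        with pytest.raises(ValueError, match="all SNPs removed"):
            qc_genotypes(make_geno(g))
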