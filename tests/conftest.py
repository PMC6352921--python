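"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

from famvar import (GenomeSpec, PedigreeSpec, Pedigree, TraitSpec,
                    simulate_genotypes, simulate_pedigree)


@pytest.fixture(scope="session")
def family_cohort():
    """~520 individuals in couple/sibling families plus singletons."""
    ped = simulate_pedigree(PedigreeSpec(
        n_couples=120, n_children_dist={1: 0.4, 2: 0.4, 3: 0.2},
        n_singletons=60, seed=41))
    geno = simulate_genotypes(
        ped, GenomeSpec(n_snps=600, n_chromosomes=3, ld_block_size=4,
                        ld_rho=0.5), seed=42)
    return ped, geno


@pytest.fixture(scope="session")
def singleton_cohort():
    """300 unrelated founders with a small marker panel."""
    ped = simulate_pedigree(PedigreeSpec(n_couples=0, n_children_dist={0: 1.0},
                                         n_singletons=300, seed=7))
    geno = simulate_genotypes(ped, GenomeSpec(n_snps=400, n_chromosomes=2),
                              seed=8)
    return ped, geno


@pytest.fixture
def three_generation_pedigree():
    """Hand-built pedigree covering parent-offspring, sibs, grandparents,
    avuncular and first-cousin relationships."""
    rows = [
        # fid iid father mother sex couple
        ("f", "A", "0", "0", 1, "c1"), ("f", "B", "0", "0", 2, "c1"),
        ("f", "C", "0", "0", 1, "c2"), ("f", "D", "0", "0", 2, "c2"),
        ("f", "E", "A", "B", 1, "c3"),  # child of A,B
        ("f", "F", "A", "B", 2, "c4"),  # full sib of E
        ("f", "G", "C", "D", 2, "c3"),  # child of C,D; spouse of E
        ("f", "X", "0", "0", 1, "c4"),  # unrelated founder; spouse of F
        ("f", "I", "E", "G", 1, "0"),   # grandchild of A,B,C,D
        ("f", "J", "F", "X", 2, "0"),   # first cousin of I (via E-F)
    ]
    return Pedigree(pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "couple_id"]))


def mc_mean_within(estimates, truth, label=""):
    """Assert the Monte-Carlo mean is within 2 MC standard errors of truth."""
    est = np.asarray(estimates, float)
    mcse = est.std(ddof=1) / np.sqrt(len(est))
    assert abs(est.mean() - truth) <= 2 * mcse + 1e-12, (
        f"{label}: mean {est.mean():.4f} not within 2*{mcse:.4f} of {truth}")
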