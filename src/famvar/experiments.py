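"""Replication experiments: simulate a family cohort with known variance
fractions, refit by REML, and summarise recovery across replicates.

These are the desk-scale experiments the package uses to validate the
variance-component machinery end to end: a couple-structured cohort whose
phenotype mixes a SNP-genetic fraction with a couple-environment fraction
(the selected two-component model of the motivating design), plus backward
stepwise selection on designs generated from known component sets.

Problem sizes (~1,500 individuals, a few thousand markers) are chosen so a
full experiment runs in minutes on a single core; docs/methods.md discusses
the choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .relmat import (build_env_matrices, build_grm, build_pedigree_matrix)
from .simulate import (GenomeSpec, PedigreeSpec, TraitSpec,
                       simulate_genotypes, simulate_pedigree,
                       simulate_phenotypes)
from .vcomp import reml_fit, stepwise_select

# generating values of the two-component (SNP + couple) recovery experiment
GC_TRUTH = {"G": 0.08, "C": 0.13}

GC_PEDIGREE = dict(n_couples=400,
                   n_children_dist={0: 0.25, 1: 0.25, 2: 0.3, 3: 0.2},
                   n_singletons=200)
GC_GENOME = GenomeSpec(n_snps=3000, n_chromosomes=10)
GC_N_CAUSAL = 600


def gc_recovery(n_reps: int = 20, seed: int = 1) -> pd.DataFrame:
    """Simulate-and-refit replicates of the SNP + couple-environment model.

    Each replicate draws a fresh couple/sibling-structured cohort
    (~1,500 individuals), genotypes and a phenotype with variance fractions
    ``GC_TRUTH``, then fits the G+C model by REML.  Returns one row per
    replicate with the fitted fractions.
    """
    rows = []
    for r in range(n_reps):
        base = seed * 10_000 + r * 3
        ped = simulate_pedigree(PedigreeSpec(**GC_PEDIGREE, seed=base))
        geno = simulate_genotypes(ped, GC_GENOME, seed=base + 1)
        ph = simulate_phenotypes(ped, geno, TraitSpec(
            var_G=GC_TRUTH["G"], var_C=GC_TRUTH["C"], n_causal=GC_N_CAUSAL,
            seed=base + 2))
        _, C, _ = build_env_matrices(ped)
        fit = reml_fit(ph["trait"].to_numpy(), None, [build_grm(geno), C])
        rows.append({"rep": r, "G": fit.estimates["G"],
                     "C": fit.estimates["C"], "n": ped.n,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def summarise_recovery(df: pd.DataFrame, component: str) -> dict:
    est = df[component].to_numpy()
    return {"mean": float(est.mean()),
            "mcse": float(est.std(ddof=1) / np.sqrt(len(est))),
            "truth": GC_TRUTH[component], "n_reps": len(est)}


# ------------------------------------------------- stepwise model recovery
# Each design states its generating fractions and the cohort scale at which
# the generating set is detectable.  Separating K from F rests entirely on
# spouse pairs (see the identifiability note in docs/methods.md), so the
# pedigree-genetic designs use a larger cohort with more couples; the
# SNP+couple design is identified already at half that size.
STEPWISE_DESIGNS = {
    "GC": dict(fractions=dict(var_G=0.25, var_C=0.20),
               n_couples=180, n_singletons=60, n_snps=1200, seed_base=20_000),
    "F": dict(fractions=dict(var_F=0.30),
              n_couples=350, n_singletons=100, n_snps=1500, seed_base=30_000),
    "GK": dict(fractions=dict(var_G=0.25, var_K=0.30),
               n_couples=350, n_singletons=100, n_snps=1500, seed_base=30_000),
}


def stepwise_recovery(design: str, n_reps: int = 5, seed: int = 1
                      ) -> list[list[str]]:
    """Backward stepwise selection from the full five-component model on
    cohorts generated from a known component subset; returns the selected
    component sets, one per replicate."""
    cfg = STEPWISE_DESIGNS[design]
    finals = []
    for r in range(n_reps):
        base = seed * cfg["seed_base"] + r * 3
        ped = simulate_pedigree(PedigreeSpec(
            n_couples=cfg["n_couples"],
            n_children_dist={1: 0.3, 2: 0.4, 3: 0.3},
            n_singletons=cfg["n_singletons"], seed=base))
        geno = simulate_genotypes(ped, GenomeSpec(n_snps=cfg["n_snps"],
                                                  n_chromosomes=4),
                                  seed=base + 1)
        ph = simulate_phenotypes(ped, geno, TraitSpec(
            **cfg["fractions"], n_causal=400, seed=base + 2))
        mats = {"G": build_grm(geno), "K": build_pedigree_matrix(ped)}
        mats["F"], mats["C"], mats["S"] = build_env_matrices(ped)
        final, _ = stepwise_select(ph["trait"].to_numpy(), None,
                                   [mats[c] for c in "GKFCS"])
        finals.append(sorted(final))
    return finals
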