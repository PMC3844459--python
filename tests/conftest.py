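"""Shared fixtures: small constructed families, toy synthetic datasets, the
independent enrichment-score oracle, and the heavy session-scoped null/power
simulation experiments used by the acceptance tests."""

from dataclasses import replace

import numpy as np
import pytest

from pathway_pdt import SimConfig, permutation_test, simulate
from pathway_pdt.family_io import (AFFECTED, UNAFFECTED, UNKNOWN,
                                   FamilyGenotypes, Member)
from pathway_pdt.synthetic_families import causal_spec_in_target

# ---------------------------------------------------------------------------
# constructed families


def make_family(parent_dosages, sib_dosages, sib_affections, family_id="F1"):
    """Build a nuclear family from dosage lists.

    ``parent_dosages``: None (parents absent) or [father_row, mother_row];
    ``sib_dosages``: list of per-sib dosage rows; -1 = missing.
    """
    members, rows = [], []
    if parent_dosages is not None:
        members.append(Member("P1", "0", "0", "1", UNKNOWN))
        members.append(Member("P2", "0", "0", "2", UNKNOWN))
        rows.extend(parent_dosages)
    for i, (dos, aff) in enumerate(zip(sib_dosages, sib_affections)):
        members.append(Member(f"S{i + 1}", "P1", "P2", "0", aff))
        rows.append(dos)
    fam = FamilyGenotypes(family_id=family_id, members=members,
                          genotypes=np.array(rows, dtype=np.int8))
    fam.validate()
    return fam


@pytest.fixture
def family_factory():
    return make_family


# ---------------------------------------------------------------------------
# independent enrichment-score oracle (naive two-loop running sum)


def es_reference(scores_desc, is_member, w):
    """Brute-force ES: recompute the running sum from scratch at every prefix."""
    n = len(scores_desc)
    n_h = sum(is_member)
    n_r = sum(scores_desc[j] ** w for j in range(n) if is_member[j])
    best = -np.inf
    for i in range(n):
        s = 0.0
        for j in range(i + 1):
            if is_member[j]:
                s += scores_desc[j] ** w / n_r
            else:
                s -= 1.0 / (n - n_h)
        best = max(best, s)
    return best


@pytest.fixture(scope="session")
def es_oracle():
    return es_reference


# ---------------------------------------------------------------------------
# toy synthetic dataset


@pytest.fixture(scope="session")
def toy_config():
    return SimConfig(n_families=15, n_sibs=3, n_chromosomes=2,
                     snps_per_chromosome=10, genes_per_chromosome=2,
                     pathway_n_genes=2, n_background_pathways=1,
                     maf=0.3, seed=7)


@pytest.fixture(scope="session")
def toy_dataset(toy_config):
    return simulate(toy_config)


# ---------------------------------------------------------------------------
# heavy session-scoped experiments (shared by acceptance tests)

NULL_DESIGN = dict(n_families=200, n_sibs=3, n_chromosomes=10,
                   snps_per_chromosome=50, genes_per_chromosome=5,
                   pathway_n_genes=24, n_background_pathways=4)
POWER_DESIGN = dict(NULL_DESIGN, n_families=500)
NULL_REPLICATES = 300
POWER_REPLICATES = 100
PERMUTATIONS = 500


def target_pvalue(dataset, perm_seed, K=PERMUTATIONS):
    results = permutation_test(dataset.families, dataset.snps, dataset.genes,
                               dataset.pathways, K=K, window_kb=5, w=1.0,
                               seed=perm_seed)
    return next(r.p_perm for r in results
                if r.pathway_name == dataset.target_pathway_name)


def null_experiment(n_reps, missing_parent_fraction, seed):
    """Permutation p-values for the target pathway over null replicates."""
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=(n_reps, 2))
    pvals = []
    for ds_seed, perm_seed in seeds:
        cfg = SimConfig(**NULL_DESIGN, seed=int(ds_seed),
                        missing_parent_fraction=missing_parent_fraction)
        pvals.append(target_pvalue(simulate(cfg), int(perm_seed)))
    return np.array(pvals)


@pytest.fixture(scope="session")
def null_pvalues():
    return null_experiment(NULL_REPLICATES, 0.0, seed=20260920)


@pytest.fixture(scope="session")
def null_pvalues_missing_parents():
    return null_experiment(NULL_REPLICATES, 0.5, seed=20260921)


@pytest.fixture(scope="session")
def power_rates():
    """Rejection rates at alpha=0.05 for OR 1.2 and 1.3, common random numbers."""
    base = SimConfig(**POWER_DESIGN, seed=0)
    seeds = np.random.default_rng(20260922).integers(0, 2 ** 31 - 1,
                                                     size=(POWER_REPLICATES, 2))
    rates = {}
    for odds_ratio in (1.2, 1.3):
        causal = causal_spec_in_target(base, n_causal=10, odds_ratio=odds_ratio)
        hits = 0
        for ds_seed, perm_seed in seeds:
            cfg = replace(base, causal=causal, seed=int(ds_seed))
            hits += target_pvalue(simulate(cfg), int(perm_seed)) <= 0.05
        rates[odds_ratio] = hits / POWER_REPLICATES
    return rates
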