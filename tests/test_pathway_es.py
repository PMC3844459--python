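"""Enrichment score, sign-flip permutation semantics, and p-value invariants."""

from dataclasses import replace

import numpy as np
import pytest

from pathway_pdt.family_io import PathwayDef
from pathway_pdt.gene_scoring import GeneScoreTable
from pathway_pdt.pathway_es import (EnrichmentInput, enrichment_score,
                                    permutation_test, permute_signs)
from pathway_pdt.pdt_stat import all_snp_statistics
from conftest import es_reference


def table_from(scores, symbols=None):
    symbols = symbols or [f"G{i + 1}" for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], symbols[i]))
    return GeneScoreTable(gene_symbols=[symbols[i] for i in order],
                          scores=np.array([scores[i] for i in order]),
                          best_snp_ids=["?"] * len(scores))


class TestEnrichmentScore:
    def test_hand_worked_instance(self, es_oracle):
        # N=4, scores 4,3,2,1 descending; pathway at ranks 1 and 3; w=1.
        # Running sum: 4/6, 4/6-1/2, 4/6-1/2+2/6, 0 -> ES = 2/3.
        table = table_from([4.0, 3.0, 2.0, 1.0])
        inp = EnrichmentInput(table, frozenset({"G1", "G3"}), 1.0)
        assert enrichment_score(inp) == pytest.approx(2 / 3, abs=1e-12)
        assert es_oracle([4, 3, 2, 1], [True, False, True, False], 1.0) == \
            pytest.approx(2 / 3, abs=1e-12)

    def test_single_top_gene_reaches_one(self):
        table = table_from([5.0, 2.0, 1.0, 0.5])
        assert enrichment_score(EnrichmentInput(table, frozenset({"G1"}))) == \
            pytest.approx(1.0, abs=1e-12)

    def test_single_bottom_gene_telescopes_to_zero(self):
        table = table_from([5.0, 2.0, 1.0, 0.5])
        assert enrichment_score(EnrichmentInput(table, frozenset({"G4"}))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            scores = rng.gamma(1.0, 2.0, n)
            n_h = int(rng.integers(1, n))
            members = frozenset(f"G{i + 1}" for i in rng.choice(n, n_h, replace=False))
            es = enrichment_score(EnrichmentInput(table_from(list(scores)), members))
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_degenerate_pathways_rejected(self):
        table = table_from([3.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(EnrichmentInput(table, frozenset({"G1", "G2"})))
        with pytest.raises(ValueError):
            enrichment_score(EnrichmentInput(table, frozenset({"NOPE"})))
        zero = table_from([3.0, 0.0])
        with pytest.raises(ValueError, match="N_R"):
            enrichment_score(EnrichmentInput(zero, frozenset({"G2"})))


class _ConstantSigns:
    """Stand-in generator yielding a fixed coin for every sign draw."""

    def __init__(self, bit):
        self.bit = bit

    def integers(self, low, high, size):
        return np.full(size, self.bit, dtype=np.int64)


class TestPermuteSigns:
    def test_identity_and_global_reflection(self):
        d = np.arange(12, dtype=float).reshape(3, 4) - 5
        chroms = ["1", "1", "2", "2"]
        np.testing.assert_array_equal(permute_signs(d, chroms, _ConstantSigns(1)), d)
        np.testing.assert_array_equal(permute_signs(d, chroms, _ConstantSigns(0)), -d)

    def test_signs_constant_within_family_chromosome(self):
        d = np.ones((5, 6))
        chroms = ["1", "1", "1", "2", "2", "2"]
        out = permute_signs(d, chroms, np.random.default_rng(0))
        # each (family, chromosome) block is uniformly +1 or -1
        assert np.all(np.abs(out) == 1)
        for f in range(5):
            assert len(set(out[f, :3])) == 1 and len(set(out[f, 3:])) == 1


class TestPermutationTest:
    def test_determinism_and_thread_invariance(self, toy_dataset):
        ds = toy_dataset
        kw = dict(K=199, seed=11, window_kb=5)
        r1 = permutation_test(ds.families, ds.snps, ds.genes, ds.pathways, **kw)
        r2 = permutation_test(ds.families, ds.snps, ds.genes, ds.pathways, **kw)
        r3 = permutation_test(ds.families, ds.snps, ds.genes, ds.pathways,
                              threads=3, **kw)
        assert r1 == r2 == r3

    def test_pvalue_invariants(self, toy_dataset):
        ds = toy_dataset
        results = permutation_test(ds.families, ds.snps, ds.genes, ds.pathways,
                                   K=199, seed=5)
        ps = [r.p_perm for r in results]
        assert ps == sorted(ps)  # output sorted by p
        for r in results:
            assert 0 < r.p_perm <= 1
            assert r.p_perm <= r.p_adjusted <= 1
            assert 0 <= r.fdr_q <= 1
            assert r.n_permutations == 199

    def test_single_admissible_pathway_adjusted_equals_raw(self, toy_dataset):
        ds = toy_dataset
        target = [p for p in ds.pathways if p.pathway_name == "TARGET"]
        (r,) = permutation_test(ds.families, ds.snps, ds.genes, target,
                                K=199, seed=5)
        assert r.p_adjusted == pytest.approx(r.p_perm)

    def test_allele_reflection_leaves_results_unchanged(self, toy_dataset):
        """Dosage -> 2 - dosage everywhere flips every z but no z**2, gene
        score, ES, or p-value (end-to-end orientation invariance)."""
        ds = toy_dataset
        reflected = []
        for fam in ds.families:
            g = np.where(fam.genotypes >= 0, 2 - fam.genotypes, -1).astype(np.int8)
            reflected.append(replace_genotypes(fam, g))
        kw = dict(K=99, seed=2)
        r1 = permutation_test(ds.families, ds.snps, ds.genes, ds.pathways, **kw)
        r2 = permutation_test(reflected, ds.snps, ds.genes, ds.pathways, **kw)
        assert r1 == r2

    def test_unknown_gene_pathway_skipped(self, toy_dataset):
        ds = toy_dataset
        pws = list(ds.pathways) + [PathwayDef("GHOST", "", ("NOPE1", "NOPE2"))]
        results = permutation_test(ds.families, ds.snps, ds.genes, pws, K=49, seed=0)
        assert "GHOST" not in {r.pathway_name for r in results}

    def test_no_admissible_pathway_is_error(self, toy_dataset):
        ds = toy_dataset
        with pytest.raises(ValueError, match="admissible"):
            permutation_test(ds.families, ds.snps, ds.genes,
                             [PathwayDef("GHOST", "", ("NOPE",))], K=9, seed=0)


def replace_genotypes(fam, genotypes):
    from pathway_pdt.family_io import FamilyGenotypes
    return FamilyGenotypes(family_id=fam.family_id, members=fam.members,
                           genotypes=genotypes)


class TestOracleAgreement:
    def test_random_instances_match_naive_reference(self, es_oracle):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 50))
            scores = np.sort(rng.gamma(1.5, 2.0, n))[::-1]
            n_h = int(rng.integers(1, n))
            member_rows = set(rng.choice(n, n_h, replace=False).tolist())
            member = [i in member_rows for i in range(n)]
            w = float(rng.choice([0.5, 1.0, 2.0]))
            table = table_from(list(scores))
            names = frozenset(table.gene_symbols[i] for i in range(n) if member[i])
            got = enrichment_score(EnrichmentInput(table, names, w))
            want = es_reference(list(table.scores),
                               [g in names for g in table.gene_symbols], w)
            assert got == pytest.approx(want, abs=1e-12)


def test_signflip_matches_explicit_transmission_rerandomization():
    """On parent-complete trios, multiplying a family's d by -1 equals
    reconstructing the untransmitted child genotype and recomputing d,
    permutation by permutation under a shared sign stream (small version
    of the full equivalence experiment)."""
    from pathway_pdt import SimConfig, simulate
    from pathway_pdt.family_io import FamilyGenotypes

    cfg = SimConfig(n_families=6, n_sibs=1, n_chromosomes=1,
                    snps_per_chromosome=5, genes_per_chromosome=1,
                    pathway_n_genes=1, n_background_pathways=0, seed=3)
    ds = simulate(cfg)
    d, results, _ = all_snp_statistics(ds.families, ds.snps)
    denom = np.sqrt([r.sum_d2 for r in results])
    chroms = [s.chromosome for s in ds.snps]
    streams = np.random.SeedSequence(99).spawn(50)
    for st_ in streams:
        rng = np.random.default_rng(st_)
        dstar = permute_signs(d, chroms, rng)
        z_flip = dstar.sum(axis=0) / np.where(denom > 0, denom, 1.0)

        rng2 = np.random.default_rng(st_)
        signs = rng2.integers(0, 2, size=(len(ds.families), 1)) * 2 - 1
        flipped = []
        for i, fam in enumerate(ds.families):
            g = fam.genotypes.copy()
            if signs[i, 0] == -1:
                f, m = g[0], g[1]
                g[2:] = f[None, :] + m[None, :] - g[2:]
            flipped.append(FamilyGenotypes(fam.family_id, fam.members, g))
        d2, res2, _ = all_snp_statistics(flipped, ds.snps)
        z_explicit = np.array([r.z for r in res2])
        np.testing.assert_array_equal(z_flip, z_explicit)
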