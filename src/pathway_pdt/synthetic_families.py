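"""Generator of ascertained nuclear-family GWAS datasets.

Produces PLINK-style ped/map files plus matching gene and pathway files
with the statistical structure family-based pathway tests are evaluated
on: LD-structured parental haplotypes, Mendelian transmission to a
sibship, an additive logistic disease model on a set of causal variants,
ascertainment on at least one affected sibling, and optional masking of
parental genotypes.

Haplotypes come from a first-order Markov model along each chromosome:
marginal minor-allele frequency ``maf`` per SNP and correlation ``rho``
between adjacent SNPs on the same haplotype
(P(1|1) = p + rho(1-p), P(1|0) = p(1-rho)); chromosomes are independent.
Children receive one whole haplotype per parent per chromosome (no
within-chromosome recombination — a documented simplification for the
short simulated segments).

Genes tile consecutive SNPs within each chromosome; the target pathway
is a fixed, evenly spread subset of genes, and background pathways of
matched size are drawn from the remaining genes.  Markers are written
with alleles A (major) / T (minor) so that dosages survive a ped/map
round trip bit-for-bit whenever the minor allele is observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .family_io import (AFFECTED, MISSING, UNAFFECTED, UNKNOWN, FamilyGenotypes,
                        GeneDef, Member, PathwayDef, SnpMeta)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic family generator.

    Defaults are the reduced test scale (10 chromosomes x 100 SNPs,
    50 genes, a 24-gene target pathway plus 4 background pathways); the
    evaluation-study scale (500 families of two parents and three
    siblings, causal minor-allele frequency 0.2, odds ratios 1.2 or 1.3,
    optionally 50% of families with missing parents) is reached by
    setting ``n_families``, ``causal`` and ``missing_parent_fraction``.
    """

    n_families: int = 500
    n_sibs: int = 3
    n_chromosomes: int = 10
    snps_per_chromosome: int = 100
    maf: float = 0.2
    rho: float = 0.8
    causal: tuple[tuple[int, float], ...] = ()  # (snp_index, odds_ratio)
    missing_parent_fraction: float = 0.0
    baseline_prevalence: float = 0.1
    genes_per_chromosome: int = 5
    pathway_n_genes: int = 24
    n_background_pathways: int = 4
    max_redraw: int = 2000
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


@dataclass
class SyntheticDataset:
    config: SimConfig
    snps: list[SnpMeta]
    families: list[FamilyGenotypes]
    genes: list[GeneDef]
    pathways: list[PathwayDef]
    target_pathway_name: str = "TARGET"


# ---------------------------------------------------------------------------
# deterministic structural layout (no randomness)

_SNP_SPACING = 10_000  # bp between adjacent simulated SNPs


def snp_metadata(config: SimConfig) -> list[SnpMeta]:
    snps = []
    for c in range(config.n_chromosomes):
        for j in range(config.snps_per_chromosome):
            snps.append(SnpMeta(snp_id=f"snp{c * config.snps_per_chromosome + j + 1}",
                                chromosome=str(c + 1),
                                position=_SNP_SPACING * (j + 1),
                                allele_a="A", allele_b="T"))
    return snps


def gene_blocks(config: SimConfig) -> list[tuple[str, str, np.ndarray]]:
    """(gene_symbol, chromosome, snp index block) tiling each chromosome."""
    blocks = []
    g = 0
    for c in range(config.n_chromosomes):
        base = c * config.snps_per_chromosome
        for part in np.array_split(np.arange(config.snps_per_chromosome),
                                   config.genes_per_chromosome):
            if part.size == 0:
                continue
            g += 1
            blocks.append((f"GENE{g:03d}", str(c + 1), base + part))
    return blocks


def target_gene_indices(config: SimConfig) -> np.ndarray:
    """Indices (into gene_blocks) of the target pathway: evenly spread genes."""
    n_genes = len(gene_blocks(config))
    if config.pathway_n_genes > n_genes:
        raise ValueError("pathway_n_genes exceeds total gene count")
    idx = np.unique(np.round(np.linspace(0, n_genes - 1,
                                         config.pathway_n_genes)).astype(int))
    if idx.size != config.pathway_n_genes:  # rounding collision fallback
        idx = np.arange(config.pathway_n_genes)
    return idx


def causal_spec_in_target(config: SimConfig, n_causal: int = 10,
                          odds_ratio: float = 1.3) -> tuple[tuple[int, float], ...]:
    """Causal variants placed inside target-pathway genes, one per gene round-robin."""
    blocks = gene_blocks(config)
    targets = [blocks[i] for i in target_gene_indices(config)]
    spec = []
    for k in range(n_causal):
        _, _, snp_block = targets[k % len(targets)]
        # mid-block placement: the causal variant sits inside its gene, away
        # from the boundary, so LD decay keeps the signal mostly within-gene
        offset = (snp_block.size // 2 + k // len(targets)) % snp_block.size
        spec.append((int(snp_block[offset]), float(odds_ratio)))
    return tuple(spec)


# ---------------------------------------------------------------------------
# simulation


def _sample_haplotypes(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """n haplotypes (n, n_snps) of 0/1 minor-allele indicators, Markov LD per chromosome."""
    p = float(config.maf)
    rho = float(config.rho)
    h = np.empty((n, config.n_snps), dtype=np.int8)
    col = 0
    for _c in range(config.n_chromosomes):
        prev = rng.random(n) < p
        h[:, col] = prev
        col += 1
        for _j in range(1, config.snps_per_chromosome):
            pr = np.where(prev, p + rho * (1 - p), p * (1 - rho))
            prev = rng.random(n) < pr
            h[:, col] = prev
            col += 1
    return h


def simulate(config: SimConfig) -> SyntheticDataset:
    """Draw one ascertained dataset; identical config -> identical dataset."""
    if not 0 <= config.missing_parent_fraction <= 1:
        raise ValueError("missing_parent_fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed)
    snps = snp_metadata(config)
    n_snps = config.n_snps

    causal_idx = np.array([i for i, _ in config.causal], dtype=int)
    log_or = np.array([np.log(o) for _, o in config.causal])
    if causal_idx.size and (causal_idx.min() < 0 or causal_idx.max() >= n_snps):
        raise ValueError("causal SNP index out of range")
    base = logit(config.baseline_prevalence)

    need = config.n_families
    kept_parents: list[np.ndarray] = []
    kept_children: list[np.ndarray] = []
    kept_aff: list[np.ndarray] = []
    total_drawn = 0
    while need > 0:
        batch = min(max(64, 4 * need), 16 * config.n_families)
        total_drawn += batch
        if total_drawn > config.max_redraw * config.n_families:
            raise RuntimeError("ascertainment failed: too few families with an "
                               "affected sibling (pathological configuration)")
        hap = _sample_haplotypes(4 * batch, config, rng).reshape(batch, 4, n_snps)
        father_h, mother_h = hap[:, :2], hap[:, 2:]
        # one paternal and one maternal coin per (family, sib, chromosome):
        # a whole parental haplotype is transmitted per chromosome.
        fchoice = rng.integers(0, 2, size=(batch, config.n_sibs, config.n_chromosomes))
        mchoice = rng.integers(0, 2, size=(batch, config.n_sibs, config.n_chromosomes))
        fchoice = np.repeat(fchoice, config.snps_per_chromosome, axis=2)
        mchoice = np.repeat(mchoice, config.snps_per_chromosome, axis=2)
        bi = np.arange(batch)[:, None, None]
        si = np.arange(n_snps)[None, None, :]
        child = (father_h[bi, fchoice, si] + mother_h[bi, mchoice, si]).astype(np.int8)

        eta = base + (child[:, :, causal_idx] @ log_or if causal_idx.size
                      else np.zeros((batch, config.n_sibs)))
        affected = rng.random((batch, config.n_sibs)) < expit(eta)
        keep = affected.any(axis=1)
        for i in np.flatnonzero(keep)[:need]:
            kept_parents.append(np.stack([father_h[i, 0] + father_h[i, 1],
                                          mother_h[i, 0] + mother_h[i, 1]]).astype(np.int8))
            kept_children.append(child[i])
            kept_aff.append(affected[i])
        need = config.n_families - len(kept_children)

    n_mask = int(np.floor(config.missing_parent_fraction * config.n_families))
    masked = set(rng.permutation(config.n_families)[:n_mask].tolist())

    families: list[FamilyGenotypes] = []
    for i in range(config.n_families):
        geno = np.vstack([kept_parents[i], kept_children[i]]).astype(np.int8)
        if i in masked:
            geno[0:2, :] = MISSING
        members = [Member("P1", "0", "0", "1", UNKNOWN),
                   Member("P2", "0", "0", "2", UNKNOWN)]
        for s in range(config.n_sibs):
            members.append(Member(f"S{s + 1}", "P1", "P2", "0",
                                  AFFECTED if kept_aff[i][s] else UNAFFECTED))
        fam = FamilyGenotypes(family_id=f"F{i + 1:05d}", members=members, genotypes=geno)
        fam.validate()
        families.append(fam)

    blocks = gene_blocks(config)
    pos = np.array([s.position for s in snps])
    genes = [GeneDef(sym, chrom, int(pos[blk[0]]), int(pos[blk[-1]]))
             for sym, chrom, blk in blocks]

    t_idx = target_gene_indices(config)
    target = PathwayDef("TARGET", "simulated target pathway",
                        tuple(blocks[i][0] for i in t_idx))
    pathways = [target]
    pool = np.array([i for i in range(len(blocks)) if i not in set(t_idx.tolist())])
    bg_size = min(config.pathway_n_genes, pool.size)
    for b in range(config.n_background_pathways):
        if bg_size < 2:
            break
        pick = rng.choice(pool, size=bg_size, replace=False)
        pathways.append(PathwayDef(f"BG{b + 1}", "background pathway",
                                   tuple(blocks[i][0] for i in sorted(pick.tolist()))))

    return SyntheticDataset(config=config, snps=snps, families=families,
                            genes=genes, pathways=pathways)


# ---------------------------------------------------------------------------
# writers (the exact dialects family_io consumes)

_GENO_STR = {0: "A A", 1: "A T", 2: "T T", MISSING: "0 0"}
_AFF_STR = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}


def write_ped_map(dataset: SyntheticDataset, ped_path, map_path) -> None:
    with open(map_path, "w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for fam in dataset.families:
            for r, m in enumerate(fam.members):
                geno = " ".join(_GENO_STR[int(g)] for g in fam.genotypes[r])
                fh.write(f"{fam.family_id} {m.person_id} {m.father_id} {m.mother_id} "
                         f"{m.sex} {_AFF_STR[m.affection]} {geno}\n")


def write_gene_file(dataset: SyntheticDataset, path) -> None:
    with open(path, "w") as fh:
        for g in dataset.genes:
            fh.write(f"{g.gene_symbol}\t{g.chromosome}\t{g.start}\t{g.end}\n")


def write_pathway_file(dataset: SyntheticDataset, path) -> None:
    with open(path, "w") as fh:
        for p in dataset.pathways:
            fh.write("\t".join([p.pathway_name, p.description, *p.gene_symbols]) + "\n")


def simulate_dataset(config: SimConfig, out_dir) -> tuple[Path, Path, Path, Path]:
    """Simulate and write ped/map/gene/pathway files; returns the four paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate(config)
    ped, mp = out / "families.ped", out / "families.map"
    gene, pw = out / "genes.txt", out / "pathways.gmt"
    write_ped_map(ds, ped, mp)
    write_gene_file(ds, gene)
    write_pathway_file(ds, pw)
    log.info("wrote synthetic dataset (%d families, %d SNPs) to %s",
             config.n_families, config.n_snps, out)
    return ped, mp, gene, pw
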