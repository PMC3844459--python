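"""Pathway enrichment score and the sign-flip permutation test.

For a pathway P, with the N ranked genes sorted by score descending
(scores r_1 >= ... >= r_N), the enrichment score is the maximum of the
weighted KS-like running sum

    ES(P) = max_{1<=i<=N} [ sum_{G_j in P, j<=i} r_j^w / N_R
                            - sum_{G_j not in P, j<=i} 1/(N - N_H) ]

where N_H is the number of pathway genes in the ranking and
N_R = sum_{G_j in P} r_j^w.  The maximum is over the signed running sum
as displayed, not its absolute value, so depleted pathways get ES near 0.

The null distribution comes from within-family permutation: exchanging
the transmitted and untransmitted parental alleles in a family negates
that family's PDT contribution D, so a permutation replicate is one
uniform sign per family (per chromosome, so that LD among SNPs on a
chromosome is preserved) applied to the retained family x SNP d-matrix.
Per-SNP denominators sqrt(sum d^2), the gene->SNP map, the ranked gene
set and every pathway's N_H are frozen across permutations; only the
scores, and hence the ranking and the ES values, are recomputed.

p_perm uses the conservative add-one rule (1 + #{ES* >= ES_obs})/(K+1) by
default; ``tie_rule="strict"`` counts strict exceedances over K with no
correction.  The familywise-adjusted p-value is a max-statistic over
per-pathway permutation-normalised ES values (Westfall-Young style), and
fdr_q is Benjamini-Hochberg over the p_perm vector.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .family_io import FamilyGenotypes, GeneDef, PathwayDef, SnpMeta
from .gene_scoring import GeneScoreTable, gene_scores, map_snps_to_genes
from .pdt_stat import all_snp_statistics

log = logging.getLogger(__name__)


@dataclass
class EnrichmentInput:
    """A ranked gene score table plus one pathway restricted to genes in it."""

    score_table: GeneScoreTable
    member_genes: frozenset[str]
    weight: float = 1.0

    @property
    def n_total(self) -> int:
        return self.score_table.N

    @property
    def n_hit(self) -> int:
        return sum(1 for g in self.score_table.gene_symbols if g in self.member_genes)


@dataclass(frozen=True)
class PathwayResult:
    pathway_name: str
    n_genes_mapped: int
    es: float
    p_perm: float
    p_adjusted: float
    fdr_q: float
    n_permutations: int


def enrichment_score(inp: EnrichmentInput) -> float:
    """Weighted KS-like running-sum enrichment score, single left-to-right pass."""
    table = inp.score_table
    n = table.N
    hit = np.array([g in inp.member_genes for g in table.gene_symbols], dtype=bool)
    n_h = int(hit.sum())
    if n_h == 0:
        raise ValueError("pathway has no genes in the ranked table")
    if n_h == n:
        raise ValueError("pathway covers every ranked gene (miss increment undefined)")
    rw = table.scores ** inp.weight
    n_r = float(rw[hit].sum())
    if n_r <= 0:
        raise ValueError("N_R = 0: every pathway gene has weighted score 0")
    inc = np.where(hit, rw / n_r, -1.0 / (n - n_h))
    return float(np.cumsum(inc).max())


def permute_signs(d_matrix: np.ndarray, chrom_of_snp: Sequence[str],
                  rng: np.random.Generator,
                  granularity: str = "chromosome") -> np.ndarray:
    """One permutation replicate of the d-matrix.

    Draws one uniform sign per (family, chromosome) — or per family with
    ``granularity="genome"`` — and multiplies every d on that chromosome by
    it.  Returns a new array; the input is untouched.
    """
    n_fam, n_snps = d_matrix.shape
    if len(chrom_of_snp) != n_snps:
        raise ValueError("chrom_of_snp length does not match d-matrix columns")
    _, inv = np.unique(np.asarray(chrom_of_snp), return_inverse=True)
    n_chrom = inv.max() + 1
    if granularity == "chromosome":
        signs = rng.integers(0, 2, size=(n_fam, n_chrom)) * 2 - 1
        return d_matrix * signs[:, inv]
    if granularity == "genome":
        signs = rng.integers(0, 2, size=(n_fam, 1)) * 2 - 1
        return d_matrix * signs
    raise ValueError(f"unknown sign granularity {granularity!r}")


def _batch_enrichment_scores(scores: np.ndarray, masks: np.ndarray,
                             w: float) -> np.ndarray:
    """ES for many score vectors at once.

    ``scores``: (n_reps, G) gene scores with the gene axis ordered by gene
    symbol ascending (so a stable descending sort breaks ties by symbol);
    ``masks``: (n_pathways, G) boolean membership.  Returns (n_reps,
    n_pathways).  A replicate where a pathway's N_R is 0 gets ES 0.
    """
    n_reps, n_genes = scores.shape
    order = np.argsort(-scores, axis=1, kind="stable")
    sorted_scores = np.take_along_axis(scores, order, axis=1)
    rw = sorted_scores ** w
    out = np.empty((n_reps, masks.shape[0]))
    for p, mask in enumerate(masks):
        hit = mask[order]
        n_h = int(mask.sum())
        n_r = (rw * hit).sum(axis=1)
        safe = np.where(n_r > 0, n_r, 1.0)
        inc = np.where(hit, rw / safe[:, None], -1.0 / (n_genes - n_h))
        out[:, p] = np.cumsum(inc, axis=1).max(axis=1)
        out[n_r <= 0, p] = 0.0
    return out


def permutation_test(families: Sequence[FamilyGenotypes],
                     snps: Sequence[SnpMeta],
                     genes: Sequence[GeneDef],
                     pathways: Sequence[PathwayDef],
                     *,
                     K: int = 2000,
                     window_kb: int = 5,
                     w: float = 1.0,
                     seed: int | None = None,
                     threads: int = 1,
                     score: str = "squared",
                     method: str = "sum",
                     tie_rule: str = "conservative",
                     sign_granularity: str = "chromosome",
                     min_pathway_genes: int = 2,
                     max_pathway_genes: int | None = None,
                     ) -> list[PathwayResult]:
    """Full pipeline: PDT statistics -> gene scores -> pathway ES -> permutation p-values.

    Results are sorted by p_perm ascending, ties by pathway name, and are
    bit-identical for a fixed seed regardless of ``threads`` (permutation k
    always consumes the k-th spawned random stream).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K < 100:
        log.warning("K=%d gives p-value resolution %.3g; small significance "
                    "levels are unresolvable", K, 1.0 / (K + 1))

    d_matrix, snp_results, _qc = all_snp_statistics(families, snps, method=method)
    gsmap = map_snps_to_genes(snps, genes, window_kb)
    table = gene_scores(gsmap, snp_results, score=score)

    # ---- frozen structure (identical in every permutation) ----------------
    gene_syms = sorted(table.gene_symbols)  # gene axis: symbol ascending
    gene_index = {g: i for i, g in enumerate(gene_syms)}
    n_genes = len(gene_syms)
    if n_genes < 2:
        raise ValueError("fewer than two ranked genes; no pathway is admissible")

    informative = np.array([r.informative for r in snp_results], dtype=bool)
    inf_cols = np.flatnonzero(informative)
    col_of_snp = -np.ones(len(snp_results), dtype=int)
    col_of_snp[inf_cols] = np.arange(inf_cols.size)
    denom = np.sqrt(np.array([snp_results[s].sum_d2 for s in inf_cols]))
    d_inf = np.ascontiguousarray(d_matrix[:, inf_cols])

    flat: list[int] = []
    starts: list[int] = []
    for g in gene_syms:
        cols = [int(col_of_snp[s]) for s in gsmap.assignments[g] if informative[s]]
        starts.append(len(flat))
        flat.extend(cols)
    flat_cols = np.array(flat, dtype=int)
    gene_starts = np.array(starts, dtype=int)

    chrom_labels = np.array([snps[s].chromosome for s in inf_cols])
    _, chrom_code = np.unique(chrom_labels, return_inverse=True)
    n_chrom = int(chrom_code.max()) + 1
    chrom_cols = [np.flatnonzero(chrom_code == c) for c in range(n_chrom)]

    obs_scores = np.zeros(n_genes)
    for sym, r in zip(table.gene_symbols, table.scores):
        obs_scores[gene_index[sym]] = r

    # ---- pathway admission ------------------------------------------------
    max_nh = max_pathway_genes if max_pathway_genes is not None else n_genes - 1
    max_nh = min(max_nh, n_genes - 1)
    admitted: list[PathwayDef] = []
    masks: list[np.ndarray] = []
    for pw in pathways:
        idx = [gene_index[g] for g in pw.gene_symbols if g in gene_index]
        n_h = len(idx)
        if n_h < max(1, min_pathway_genes) or n_h > max_nh:
            log.info("pathway %s skipped: %d mapped genes outside [%d, %d]",
                     pw.pathway_name, n_h, max(1, min_pathway_genes), max_nh)
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        if float((obs_scores[mask] ** w).sum()) <= 0:
            log.warning("pathway %s skipped: N_R = 0 (all member gene scores are 0)",
                        pw.pathway_name)
            continue
        admitted.append(pw)
        masks.append(mask)
    if not admitted:
        raise ValueError("no admissible pathway after mapping and size filtering")
    mask_arr = np.array(masks)

    es_obs = _batch_enrichment_scores(obs_scores[None, :], mask_arr, w)[0]

    # ---- permutations -----------------------------------------------------
    streams = np.random.SeedSequence(seed).spawn(K)
    n_fam = d_inf.shape[0]

    def run_block(k0: int, k1: int) -> np.ndarray:
        nk = k1 - k0
        if sign_granularity == "chromosome":
            signs = np.empty((nk, n_fam, n_chrom))
            for j in range(nk):
                rng = np.random.default_rng(streams[k0 + j])
                signs[j] = rng.integers(0, 2, size=(n_fam, n_chrom)) * 2 - 1
            zstar = np.empty((nk, d_inf.shape[1]))
            for c in range(n_chrom):
                cols = chrom_cols[c]
                zstar[:, cols] = signs[:, :, c] @ d_inf[:, cols]
        elif sign_granularity == "genome":
            signs = np.empty((nk, n_fam))
            for j in range(nk):
                rng = np.random.default_rng(streams[k0 + j])
                signs[j] = rng.integers(0, 2, size=n_fam) * 2 - 1
            zstar = signs @ d_inf
        else:
            raise ValueError(f"unknown sign granularity {sign_granularity!r}")
        zstar /= denom
        vals = zstar ** 2 if score == "squared" else np.abs(zstar)
        gscores = np.maximum.reduceat(vals[:, flat_cols], gene_starts, axis=1)
        return _batch_enrichment_scores(gscores, mask_arr, w)

    n_blocks = max(1, min(K, threads * 4))
    bounds = np.linspace(0, K, n_blocks + 1).astype(int)
    blocks = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            pieces = list(pool.map(lambda ab: run_block(*ab), blocks))
    else:
        pieces = [run_block(a, b) for a, b in blocks]
    es_perm = np.vstack(pieces)  # (K, n_pathways)

    # ---- p-values ---------------------------------------------------------
    if tie_rule == "conservative":
        p_perm = (1.0 + (es_perm >= es_obs[None, :]).sum(axis=0)) / (K + 1)
    elif tie_rule == "strict":
        p_perm = (es_perm > es_obs[None, :]).sum(axis=0) / K
    else:
        raise ValueError(f"unknown tie rule {tie_rule!r}")

    mu = es_perm.mean(axis=0)
    sd = es_perm.std(axis=0, ddof=1) if K > 1 else np.zeros_like(mu)
    safe_sd = np.where(sd > 0, sd, np.inf)  # degenerate pathway -> NES 0
    nes_obs = (es_obs - mu) / safe_sd
    nes_perm = (es_perm - mu[None, :]) / safe_sd[None, :]
    max_stat = nes_perm.max(axis=1)
    if tie_rule == "conservative":
        p_adj = (1.0 + (max_stat[:, None] >= nes_obs[None, :]).sum(axis=0)) / (K + 1)
    else:
        p_adj = (max_stat[:, None] > nes_obs[None, :]).sum(axis=0) / K
    p_adj = np.maximum(p_adj, p_perm)

    fdr_q = multipletests(p_perm, method="fdr_bh")[1]

    results = [PathwayResult(pathway_name=pw.pathway_name,
                             n_genes_mapped=int(mask_arr[i].sum()),
                             es=float(es_obs[i]),
                             p_perm=float(p_perm[i]),
                             p_adjusted=float(p_adj[i]),
                             fdr_q=float(fdr_q[i]),
                             n_permutations=K)
               for i, pw in enumerate(admitted)]
    results.sort(key=lambda r: (r.p_perm, r.pathway_name))
    return results
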