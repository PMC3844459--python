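"""SNP-to-gene assignment and gene scores.

A SNP is assigned to a gene when it lies inside the gene or within a
flanking window of ``window_kb`` kilobases on either side (to catch
regulatory variants); 5 kb is the default, 20 kb the common alternative.
A SNP may belong to several overlapping genes.

The gene score is the largest squared PDT statistic (``z**2``, a 1-df
chi-square-scale quantity, so the gene's best SNP corresponds to its
minimum two-sided p-value) over the gene's informative SNPs.  ``|z|`` is
available behind a flag; it ranks genes identically but changes enrichment
score values.  Uninformative SNPs (``sum_d2 == 0``) are excluded from the
max rather than scored 0, so a monomorphic SNP can never be a gene's best
SNP, and genes with no informative SNP are dropped from the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .family_io import GeneDef, SnpMeta
from .pdt_stat import SnpPdtResult

log = logging.getLogger(__name__)


@dataclass
class GeneSnpMap:
    """Mapping gene symbol -> sorted array of SNP indices, at a fixed window."""

    window_kb: int
    assignments: dict[str, np.ndarray]


@dataclass
class GeneScoreTable:
    """Genes ranked by score, descending; ties broken by gene symbol ascending.

    ``N`` (the number of ranked genes, i.e. genes with at least one
    informative SNP) is the universe size the enrichment score walks.
    """

    gene_symbols: list[str]
    scores: np.ndarray
    best_snp_ids: list[str]

    @property
    def N(self) -> int:
        return len(self.gene_symbols)


def map_snps_to_genes(snps: Sequence[SnpMeta], genes: Sequence[GeneDef],
                      window_kb: int = 5) -> GeneSnpMap:
    """Assign SNPs to genes with a +/- window_kb kb window, inclusive ends.

    Genes with zero assigned SNPs are dropped; if no gene receives a SNP
    (e.g. chromosome label mismatch between map and gene file) this is a
    hard error because there is nothing to rank.
    """
    if window_kb < 0:
        raise ValueError("window_kb must be >= 0")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chromosome for s in snps}:
        idx = np.array([i for i, s in enumerate(snps) if s.chromosome == chrom])
        pos = np.array([snps[i].position for i in idx])
        order = np.argsort(pos, kind="stable")
        by_chrom[chrom] = (pos[order], idx[order])

    pad = 1000 * window_kb
    assignments: dict[str, np.ndarray] = {}
    gene_chroms = {g.chromosome for g in genes}
    for gene in genes:
        if gene.chromosome not in by_chrom:
            continue
        pos, idx = by_chrom[gene.chromosome]
        lo = np.searchsorted(pos, gene.start - pad, side="left")
        hi = np.searchsorted(pos, gene.end + pad, side="right")
        if hi > lo:
            assignments[gene.gene_symbol] = np.sort(idx[lo:hi])
    if not assignments:
        raise ValueError("no gene received any SNP; check that chromosome labels "
                         "in the map file and the gene file agree literally")
    if not gene_chroms & set(by_chrom):
        log.warning("no chromosome label shared between gene file and map file")
    dropped = len(genes) - len(assignments)
    if dropped:
        log.info("%d gene(s) with zero assigned SNPs dropped", dropped)
    return GeneSnpMap(window_kb=window_kb, assignments=assignments)


def gene_scores(gsmap: GeneSnpMap, snp_results: Sequence[SnpPdtResult],
                score: str = "squared",
                snps: Sequence[SnpMeta] | None = None) -> GeneScoreTable:
    """Reduce per-SNP statistics to one score per gene and rank descending.

    ``best_snp_ids`` holds marker names when ``snps`` is given, otherwise
    the SNP index as a string.
    """
    if score not in ("squared", "abs"):
        raise ValueError(f"unknown score kind {score!r}")
    z = np.array([r.z for r in snp_results])
    informative = np.array([r.informative for r in snp_results], dtype=bool)
    vals = z ** 2 if score == "squared" else np.abs(z)

    entries: list[tuple[float, str, str]] = []
    for symbol, snp_idx in gsmap.assignments.items():
        cols = snp_idx[informative[snp_idx]]
        if cols.size == 0:
            continue
        v = vals[cols]
        best = int(cols[int(np.argmax(v))])  # cols ascending -> ties take smallest index
        entries.append((float(v.max()), symbol, best))
    if not entries:
        raise ValueError("no gene has an informative SNP; nothing to rank")
    entries.sort(key=lambda e: (-e[0], e[1]))
    return GeneScoreTable(
        gene_symbols=[sym for _, sym, _ in entries],
        scores=np.array([r for r, _, _ in entries]),
        best_snp_ids=[snps[b].snp_id if snps is not None else str(b)
                      for _, _, b in entries],
    )


def write_gene_scores(table: GeneScoreTable, gsmap: GeneSnpMap, path) -> None:
    """Debug TSV dump of the ranked gene score table."""
    with open(path, "w") as fh:
        fh.write("gene\tscore\tbest_snp\tn_snps\n")
        for sym, r, best in zip(table.gene_symbols, table.scores, table.best_snp_ids):
            fh.write(f"{sym}\t{r:.6g}\t{best}\t{len(gsmap.assignments[sym])}\n")
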