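"""Readers and writers for the file dialects of family-based pathway analysis.

Input formats:

* PLINK text pedigree (``.ped``) and marker map (``.map``) files holding
  nuclear-family genotypes.  Genotypes are recoded to allele-B dosage
  (0/1/2 copies of the lexicographically larger observed allele, ``-1``
  for missing).
* A flat gene location file: ``symbol  chromosome  start  end`` per line,
  1-based inclusive coordinates.
* A GMT-style pathway file: ``name<TAB>description<TAB>gene1<TAB>gene2...``
  per line.

Chromosome labels are opaque strings and must agree literally between the
map file and the gene file; mismatches surface downstream as zero mapped
SNPs plus a logged warning, never as silent normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

#: dosage code for a missing genotype
MISSING: int = -1

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

# PLINK phenotype convention: 2 = affected, 1 = unaffected, 0/-9 = unknown.
_AFFECTION_CODES = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


@dataclass(frozen=True)
class SnpMeta:
    """Marker metadata for one biallelic SNP.

    ``allele_b`` is the allele whose dosage is counted (the lexicographically
    larger observed allele); ``allele_a`` is the other observed allele, or a
    ``"."`` placeholder when the SNP is monomorphic in the data.
    """

    snp_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class Member:
    person_id: str
    father_id: str
    mother_id: str
    sex: str
    affection: str  # AFFECTED / UNAFFECTED / UNKNOWN


@dataclass(eq=False)
class FamilyGenotypes:
    """One nuclear family: members plus an allele-B dosage matrix.

    ``genotypes`` has shape ``(n_members, n_snps)`` with values 0/1/2 and
    ``MISSING`` (-1); rows follow ``members`` order.
    """

    family_id: str
    members: list[Member]
    genotypes: np.ndarray

    def parent_indices(self) -> list[int]:
        """Rows of members who are referenced as a father or mother."""
        referenced = set()
        for m in self.members:
            if m.father_id != "0":
                referenced.add(m.father_id)
            if m.mother_id != "0":
                referenced.add(m.mother_id)
        return [i for i, m in enumerate(self.members) if m.person_id in referenced]

    def sibling_indices(self) -> list[int]:
        parents = set(self.parent_indices())
        return [i for i in range(len(self.members)) if i not in parents]

    def validate(self) -> None:
        """Check the single-nuclear-family invariants; raise ValueError if violated."""
        fid = self.family_id
        ids = [m.person_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"family {fid}: duplicate person IDs")
        if self.genotypes.shape[0] != len(self.members):
            raise ValueError(f"family {fid}: genotype matrix does not match member count")
        parent_rows = self.parent_indices()
        if len(parent_rows) > 2:
            raise ValueError(f"family {fid}: more than two members referenced as parents "
                             "(not a single nuclear family)")
        for i in parent_rows:
            m = self.members[i]
            if m.father_id != "0" or m.mother_id != "0":
                raise ValueError(f"family {fid}: member {m.person_id} is both a parent and "
                                 "a child (three generations; not a nuclear family)")
        sib_rows = self.sibling_indices()
        if not sib_rows:
            raise ValueError(f"family {fid}: no non-parent members")
        pairs = {(self.members[i].father_id, self.members[i].mother_id) for i in sib_rows}
        if len(pairs) > 1:
            raise ValueError(f"family {fid}: siblings do not share the same two parent IDs "
                             "(not a single nuclear family)")


@dataclass(frozen=True)
class GeneDef:
    """Gene location: 1-based inclusive interval on an (opaque) chromosome label."""

    gene_symbol: str
    chromosome: str
    start: int
    end: int


@dataclass(frozen=True)
class PathwayDef:
    pathway_name: str
    description: str
    gene_symbols: tuple[str, ...]


def read_ped_map(ped_path, map_path) -> tuple[list[FamilyGenotypes], list[SnpMeta]]:
    """Read PLINK text ped/map files into the domain model.

    Families are grouped by family ID and returned sorted by family ID so
    that results never depend on input row order.  Allele codes are inferred
    per SNP from the alleles observed anywhere in the file; more than two
    observed alleles is a hard error.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows = _read_map(map_path)
    n_snps = len(map_rows)

    rows: list[list[str]] = []
    line_numbers: list[int] = []
    expected = 6 + 2 * n_snps
    with ped_path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise ValueError(f"{ped_path}: line {ln}: expected {expected} "
                                 f"whitespace-delimited fields, got {len(fields)}")
            rows.append(fields)
            line_numbers.append(ln)
    if not rows:
        raise ValueError(f"{ped_path}: empty ped file")

    arr = np.array(rows, dtype="U32")
    alleles = arr[:, 6:].reshape(len(rows), n_snps, 2)

    # PLINK missing convention: both alleles "0"; one "0" is malformed.
    is_zero = alleles == "0"
    half = is_zero[:, :, 0] ^ is_zero[:, :, 1]
    if half.any():
        r, s = np.argwhere(half)[0]
        raise ValueError(f"{ped_path}: line {line_numbers[r]}: half-missing genotype at "
                         f"SNP {map_rows[s][1]} (one allele '0')")
    missing = is_zero[:, :, 0] & is_zero[:, :, 1]

    snps: list[SnpMeta] = []
    allele_b = np.empty(n_snps, dtype="U32")
    for s, (chrom, snp_id, pos) in enumerate(map_rows):
        obs = np.unique(alleles[:, s, :])
        obs = sorted(a for a in obs if a != "0")
        if len(obs) > 2:
            raise ValueError(f"{ped_path}: SNP {snp_id}: more than two alleles observed "
                             f"({', '.join(obs)})")
        if len(obs) == 2:
            a, b = obs
        elif len(obs) == 1:
            a, b = ".", obs[0]
        else:
            a, b = ".", "?"
        allele_b[s] = b
        snps.append(SnpMeta(snp_id=snp_id, chromosome=chrom, position=pos,
                            allele_a=a, allele_b=b))

    dosage = (alleles == allele_b[None, :, None]).sum(axis=2).astype(np.int8)
    dosage[missing] = MISSING

    # Group rows into families preserving within-family row order.
    by_family: dict[str, list[int]] = {}
    for i, fields in enumerate(rows):
        by_family.setdefault(fields[0], []).append(i)

    families: list[FamilyGenotypes] = []
    for fid in sorted(by_family):
        idx = by_family[fid]
        members = []
        for i in idx:
            f = rows[i]
            if f[5] not in _AFFECTION_CODES:
                raise ValueError(f"{ped_path}: line {line_numbers[i]}: unknown affection "
                                 f"code {f[5]!r} (expected 2/1/0/-9)")
            members.append(Member(person_id=f[1], father_id=f[2], mother_id=f[3],
                                  sex=f[4], affection=_AFFECTION_CODES[f[5]]))
        fam = FamilyGenotypes(family_id=fid, members=members, genotypes=dosage[idx])
        fam.validate()
        families.append(fam)

    log.info("read %d families, %d SNPs from %s / %s",
             len(families), n_snps, ped_path, map_path)
    return families, snps


def _read_map(map_path: Path) -> list[tuple[str, str, int]]:
    rows: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    with map_path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(f"{map_path}: line {ln}: expected 4 fields "
                                 f"(chr, snp_id, cM, bp), got {len(fields)}")
            chrom, snp_id, _cm, bp = fields
            try:
                pos = int(bp)
            except ValueError:
                raise ValueError(f"{map_path}: line {ln}: non-integer bp position {bp!r}")
            if pos <= 0:
                raise ValueError(f"{map_path}: line {ln}: non-positive bp position {pos}")
            if snp_id in seen:
                raise ValueError(f"{map_path}: line {ln}: duplicate SNP ID {snp_id!r}")
            seen.add(snp_id)
            rows.append((chrom, snp_id, pos))
    return rows


def read_gene_file(path) -> list[GeneDef]:
    """Read a 4-column gene location file; returns genes sorted by (chromosome, start)."""
    path = Path(path)
    genes: list[GeneDef] = []
    seen: set[str] = set()
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}: line {ln}: expected 4 fields "
                                 f"(symbol, chromosome, start, end), got {len(fields)}")
            symbol, chrom, start_s, end_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates "
                                 f"{start_s!r}/{end_s!r}")
            if start > end:
                raise ValueError(f"{path}: line {ln}: gene {symbol}: start {start} > end {end}")
            if symbol in seen:
                raise ValueError(f"{path}: line {ln}: duplicated gene symbol {symbol!r}")
            seen.add(symbol)
            genes.append(GeneDef(gene_symbol=symbol, chromosome=chrom, start=start, end=end))
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def read_pathway_file(path) -> list[PathwayDef]:
    """Read a GMT-style pathway file (name, description, then gene symbols, tab-delimited).

    Duplicate gene symbols within a pathway are removed preserving first
    occurrence; a line with no gene fields is skipped with a warning.
    """
    path = Path(path)
    pathways: list[PathwayDef] = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            name = fields[0]
            description = fields[1] if len(fields) > 1 else ""
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                log.warning("%s: line %d: pathway %r has no gene fields; skipped",
                            path, ln, name)
                continue
            pathways.append(PathwayDef(pathway_name=name, description=description,
                                       gene_symbols=genes))
    return pathways


def write_results(results: Sequence, path) -> None:
    """Write pathway results as a TSV sorted by permutation p-value, ties by name."""
    path = Path(path)
    ordered = sorted(results, key=lambda r: (r.p_perm, r.pathway_name))
    with path.open("w") as fh:
        fh.write("pathway\tn_genes_mapped\tES\tp_perm\tp_adjusted\tfdr_q\n")
        for r in ordered:
            fh.write(f"{r.pathway_name}\t{r.n_genes_mapped}\t{r.es:.6g}\t"
                     f"{r.p_perm:.6g}\t{r.p_adjusted:.6g}\t{r.fdr_q:.6g}\n")
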