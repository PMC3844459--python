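"""Per-family and per-SNP pedigree disequilibrium test (PDT) statistics.

The PDT combines two kinds of informative units within a nuclear family:

* a *triad* — both parents genotyped plus one genotyped affected child —
  contributing the transmitted-minus-untransmitted allele-B count
  ``X_T = 2c - f - m`` (c, f, m = allele-B dosages of child, father, mother);
* a *discordant sib pair* (DSP) — one affected and one unaffected genotyped
  sibling — contributing ``X_S = (affected dosage) - (unaffected dosage)``,
  over all affected x unaffected pairs.

A family's contribution ``D`` is the sum of its unit contributions, and the
sum-PDT statistic for a SNP over families is ``Z = sum(D_i) / sqrt(sum(D_i^2))``.
Swapping every transmitted allele with its untransmitted partner within a
family negates ``D`` — the sign-change identity the permutation engine
exploits.

Triads are only scored when both parents are genotyped; a Mendelian-
inconsistent triad contributes 0 and is tallied in the QC summary rather
than raising, since real ped files contain genotyping errors.  Unknown-
phenotype siblings join no unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .family_io import AFFECTED, UNAFFECTED, FamilyGenotypes, SnpMeta

log = logging.getLogger(__name__)

_X_LABELS = {"X", "x", "23", "chrX", "chrx"}


@dataclass(frozen=True)
class SnpFamilyContribution:
    """One family's PDT summand D for one SNP, plus its informative-unit count."""

    family_index: int
    snp_index: int
    d: float
    n_units: int


@dataclass(frozen=True)
class SnpPdtResult:
    snp_index: int
    z: float
    sum_d: float
    sum_d2: float
    informative: bool


@dataclass(frozen=True)
class PdtQc:
    """Quality-control tallies accumulated while computing contributions."""

    n_mendelian_inconsistent: int = 0


def _family_d_vectors(family: FamilyGenotypes) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (d, n_units, mendelian_error) vectors for one family."""
    geno = family.genotypes.astype(np.int32)
    n_snps = geno.shape[1]
    d = np.zeros(n_snps, dtype=np.int32)
    n_units = np.zeros(n_snps, dtype=np.int32)
    mendel = np.zeros(n_snps, dtype=np.int32)

    sib_rows = family.sibling_indices()
    aff = [i for i in sib_rows if family.members[i].affection == AFFECTED]
    unaff = [i for i in sib_rows if family.members[i].affection == UNAFFECTED]

    parent_rows = family.parent_indices()
    if len(parent_rows) == 2:
        f_dos, m_dos = geno[parent_rows[0]], geno[parent_rows[1]]
        both = (f_dos >= 0) & (m_dos >= 0)
        f_safe = np.where(f_dos >= 0, f_dos, 0)
        m_safe = np.where(m_dos >= 0, m_dos, 0)
        # transmissible allele-B count from a parent with dosage g is in
        # [g//2, (g+1)//2]; a child dosage outside the sum of those ranges
        # is Mendelian-inconsistent.
        t_min = f_safe // 2 + m_safe // 2
        t_max = (f_safe + 1) // 2 + (m_safe + 1) // 2
        for a in aff:
            c = geno[a]
            present = both & (c >= 0)
            consistent = (c >= t_min) & (c <= t_max)
            valid = present & consistent
            d += np.where(valid, 2 * c - f_safe - m_safe, 0)
            n_units += valid
            mendel += present & ~consistent

    if aff and unaff:
        a_mat = geno[aff]
        u_mat = geno[unaff]
        a_ok = a_mat >= 0
        u_ok = u_mat >= 0
        sum_a = (a_mat * a_ok).sum(axis=0)
        sum_u = (u_mat * u_ok).sum(axis=0)
        cnt_a = a_ok.sum(axis=0)
        cnt_u = u_ok.sum(axis=0)
        # sum over all affected x unaffected genotyped pairs of (d_a - d_u)
        d += sum_a * cnt_u - sum_u * cnt_a
        n_units += cnt_a * cnt_u

    return d, n_units, mendel


def family_contribution(family: FamilyGenotypes, snp_index: int,
                        family_index: int = 0) -> SnpFamilyContribution:
    """The family's PDT summand D at one SNP (sum of triad and DSP summands)."""
    d, n_units, _ = _family_d_vectors(family)
    return SnpFamilyContribution(family_index=family_index, snp_index=snp_index,
                                 d=float(d[snp_index]), n_units=int(n_units[snp_index]))


def snp_statistic(contributions: Sequence[SnpFamilyContribution],
                  method: str = "sum") -> SnpPdtResult:
    """Combine per-family contributions at one SNP into the PDT statistic.

    ``method="sum"`` is the sum-PDT ``Z = sum(D_i)/sqrt(sum(D_i^2))``;
    ``method="avg"`` first divides each family's D by its number of
    informative units.
    """
    if not contributions:
        raise ValueError("no contributions supplied")
    snp_index = contributions[0].snp_index
    if any(c.snp_index != snp_index for c in contributions):
        raise ValueError("contributions refer to different SNPs")
    if method == "sum":
        ds = np.array([c.d for c in contributions], dtype=float)
    elif method == "avg":
        ds = np.array([c.d / c.n_units if c.n_units else 0.0 for c in contributions])
    else:
        raise ValueError(f"unknown PDT method {method!r}")
    sum_d = float(ds.sum())
    sum_d2 = float((ds ** 2).sum())
    informative = sum_d2 > 0
    z = sum_d / math.sqrt(sum_d2) if informative else 0.0
    return SnpPdtResult(snp_index=snp_index, z=z, sum_d=sum_d, sum_d2=sum_d2,
                        informative=informative)


def all_snp_statistics(families: Sequence[FamilyGenotypes],
                       snps: Sequence[SnpMeta] | None = None,
                       method: str = "sum",
                       ) -> tuple[np.ndarray, list[SnpPdtResult], PdtQc]:
    """Family x SNP matrix of PDT contributions plus per-SNP statistics.

    The returned d-matrix (dtype float64) is the sufficient statistic for
    the whole permutation procedure: flipping the sign of row f at the SNPs
    of one chromosome reproduces the statistics after exchanging transmitted
    and untransmitted alleles in family f on that chromosome.  With
    ``method="avg"`` the matrix holds D/n_units per family.
    """
    if not families:
        raise ValueError("no families supplied")
    n_snps = families[0].genotypes.shape[1]
    if snps is not None and len(snps) != n_snps:
        raise ValueError(f"marker list length {len(snps)} does not match "
                         f"genotype columns {n_snps}")
    d_matrix = np.zeros((len(families), n_snps), dtype=np.float64)
    mendel_total = 0
    for i, fam in enumerate(families):
        d, n_units, mendel = _family_d_vectors(fam)
        mendel_total += int(mendel.sum())
        if method == "avg":
            d_matrix[i] = np.where(n_units > 0, d / np.maximum(n_units, 1), 0.0)
        elif method == "sum":
            d_matrix[i] = d
        else:
            raise ValueError(f"unknown PDT method {method!r}")
    if mendel_total:
        log.warning("%d Mendelian-inconsistent triad observations contributed 0",
                    mendel_total)
    if snps is not None:
        x_snps = [s.snp_id for s in snps if s.chromosome in _X_LABELS]
        if x_snps:
            log.warning("%d SNP(s) on X processed with the autosomal PDT formula",
                        len(x_snps))

    sum_d = d_matrix.sum(axis=0)
    sum_d2 = (d_matrix ** 2).sum(axis=0)
    informative = sum_d2 > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(informative, sum_d / np.sqrt(np.where(informative, sum_d2, 1.0)), 0.0)
    results = [SnpPdtResult(snp_index=s, z=float(z[s]), sum_d=float(sum_d[s]),
                            sum_d2=float(sum_d2[s]), informative=bool(informative[s]))
               for s in range(n_snps)]
    return d_matrix, results, PdtQc(n_mendelian_inconsistent=mendel_total)
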