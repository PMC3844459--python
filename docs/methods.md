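# Methods

## Statistical model

### Per-SNP statistic

The package implements the sum-form PDT. For family *i* and a biallelic
SNP, the family contribution is

    D_i = Σ_triads (2c − f − m) + Σ_DSPs (x_A − x_U)

with dosages counted for allele B, the lexicographically larger observed
allele (orientation is irrelevant downstream because gene scores use z²;
an end-to-end test asserts invariance under dosage reflection). Over
families, `Z = Σ D_i / sqrt(Σ D_i²)`; under the null of no transmission
distortion Z is asymptotically standard normal, which the suite verifies
empirically on null simulations. The avg-PDT variant (each family's D
divided by its number of informative units before summing) is available
via `method="avg"`.

Scoring rules, chosen where the family data are imperfect:

* Triads require **both** parents genotyped at the SNP. Transmissions
  from a single genotyped parent are not scored: reconstructing the
  missing parent's transmission is ambiguous, and skipping it is
  conservative.
* A Mendelian-inconsistent triad contributes 0 and is tallied in a logged
  QC summary rather than raising — real ped files contain genotyping
  errors and a hard failure per bad call would make the tool unusable.
* Discordant sib pairs are all affected × unaffected pairs of genotyped
  siblings; unknown-phenotype siblings join no unit.
* X-chromosome SNPs are processed with the autosomal formula and a
  logged warning; no sex-specific statistic is implemented.

### Gene scores

A SNP belongs to a gene when `gene.start − 1000k ≤ pos ≤ gene.end + 1000k`
(1-based inclusive, PLINK map convention); `k = 5` kb by default with
20 kb the common alternative for regulatory coverage. The gene score is
`r_j = max z²` over the gene's *informative* SNPs (`Σ D² > 0`).
Uninformative SNPs are excluded from the max rather than scored 0, so a
monomorphic marker can never represent a gene; genes with no informative
SNP are dropped from the ranking. z² rather than |z| is the default
because the selected "largest statistic" stands in for the gene's minimum
two-sided p-value, and the squared form is on the familiar 1-df
chi-square scale; |z| is available behind a flag and produces the same
ranking but different ES values.

### Enrichment score and permutation null

ES(P) is the maximum of the signed weighted running sum over the
descending gene ranking (hit increment `r^w / N_R`, miss decrement
`1/(N − N_H)`, default `w = 1`), *not* of its absolute value — depleted
pathways therefore get ES near 0 and large p-values; this is a known
limitation of the signed form, kept deliberately.

A permutation replicate draws one uniform ±1 sign per family per
chromosome and applies it to the retained family × SNP d-matrix
(chromosome-simultaneous flips preserve LD among a chromosome's SNPs; a
single genome-wide sign per family is available behind a flag). The
per-SNP denominators, the gene→SNP map, the informative-SNP set, the
ranked gene universe N and every pathway's N_H are frozen across
permutations; only scores, ranking and ES are recomputed, so gene and
pathway sizes cannot bias the test under the null.

* `p_perm = (1 + #{ES* ≥ ES_obs}) / (K + 1)` by default. Counting ties as
  exceedances plus the add-one correction is conservative and guarantees
  p > 0; `tie_rule="strict"` gives the plain `#{ES* > ES_obs} / K`
  alternative.
* The familywise-adjusted p-value is a Westfall–Young max-statistic:
  each pathway's ES stream is normalised by its own permutation mean and
  standard deviation (making pathways of different sizes comparable), and
  the observed normalised score is referred to the permutation
  distribution of the across-pathway maximum. A pathway whose permutation
  ES distribution is degenerate (sd = 0) is given normalised score 0.
* `fdr_q` is Benjamini–Hochberg step-up over the p_perm vector
  (statsmodels implementation).
* Defaults `K = 2000` and `w = 1`. A warning is logged when K < 100,
  where the p-value grid becomes too coarse for common significance
  levels.

Pathways are admissible when, after restriction to ranked genes,
`2 ≤ N_H ≤ N − 1` (configurable) and the observed `N_R > 0`; others are
skipped with a logged reason.

### Determinism and parallelism

Permutation k always consumes the k-th stream spawned from the seed
(`numpy.random.SeedSequence(seed).spawn(K)`), so results are bit-identical
for any thread count; threads partition permutation blocks via a thread
pool (the heavy inner steps are BLAS/numpy calls that release the GIL).
Families are canonically ordered by family ID at read time and gene ties
are broken by symbol, making the output invariant to input row order.

## Synthetic-data generator

`synthetic_families` emulates the structure of family-GWAS evaluation
studies without any external download:

* **Haplotypes**: first-order Markov chain per chromosome with marginal
  minor-allele frequency `maf` (default 0.2, the typical common-variant
  frequency used in power evaluations) and adjacent-SNP correlation
  `rho` (default 0.8, a moderately strong LD block structure); SNPs are
  spaced 10 kb apart, chromosomes independent.
* **Families**: two parents (4 haplotypes), `n_sibs` children (default 3)
  each receiving one whole parental haplotype per chromosome — no
  within-chromosome recombination, a documented simplification for these
  short segments.
* **Phenotypes**: additive logistic model,
  `logit P(aff) = logit(prevalence) + Σ dosage_c · ln(OR_c)` with
  baseline prevalence 0.1; parents' phenotypes are written as unknown
  since parental affection enters no PDT unit.
* **Ascertainment**: families are redrawn until ≥ 1 sibling is affected,
  with a bounded total number of redraws (hard error on pathological
  configurations).
* **Missing parents**: a `missing_parent_fraction` of families
  (⌊f·n⌋, chosen at random) have both parents' genotypes masked,
  leaving those families DSP-only.
* **Genes and pathways**: genes tile consecutive SNPs within each
  chromosome (default 5 genes/chromosome × 10 chromosomes = 50 genes);
  the target pathway is a fixed, evenly spread 24-gene subset, and
  background pathways of matched size are drawn from the remaining
  genes. Causal variants (default ten, odds ratio 1.2 or 1.3) are placed
  mid-gene inside distinct target genes, so that LD decay keeps each
  signal mostly within its gene — boundary placement would leak
  association into the adjacent background gene through the Markov chain,
  which has no analogue when genes are genuinely separated loci.

What the generator does **not** emulate: realistic recombination maps and
demography, allele-frequency spectra, chip-scale marker density
(a 550k-SNP design is a configuration, not a test fixture), or empirical
HapMap LD. Passing calibration tests on these data therefore demonstrate
correctness of the statistic and permutation machinery under a generic
LD structure, not performance guarantees on any particular real cohort.

## Problem sizes used in the checks

The calibration experiments run 300 null replicates of 200 families
(2 parents + 3 siblings) on 10 chromosomes × 50 SNPs with K = 500
permutations, testing the 24-gene target pathway at the 0.05 and 0.01
levels against the upper 99% binomial bound; the missing-parent variant
repeats this with half the families parent-masked. The power experiment
keeps the evaluation design's 500 families (at 200 families a
10-variant OR ≤ 1.3 signal is essentially undetectable by any
competitive test) with 100 replicates per odds ratio, using common
random numbers across the OR = 1.2 and OR = 1.3 arms so the monotonicity
comparison is paired. Null p-value uniformity is checked with a
Kolmogorov–Smirnov band at the 1% level.

## Numerical choices and edge cases

* Dosages are small integers; `z` is computed in float64 from integer
  sums, so the sign-flip shortcut and explicit transmitted/untransmitted
  re-randomization agree bit-for-bit (asserted on a trio fixture).
* Ranking ties: stable descending sort on scores with the gene axis
  pre-sorted by symbol — deterministic tie-breaking by gene symbol.
  Best-SNP ties within a gene take the smallest SNP index.
* A monomorphic SNP's allele orientation is unknowable from a ped file;
  the single observed allele becomes allele B with a `.` placeholder
  partner. Such SNPs are uninformative and never affect results.
* Half-missing genotypes (one allele `0`) are a hard parse error naming
  the line, as is any field-count mismatch, >2 observed alleles at a
  SNP, non-nuclear family structure, or unknown affection code.

## Known limitations

* Depletion is not tested (signed running-max ES, see above).
* No leading-edge gene reporting.
* Single-parent transmissions are never scored.
* Extended multigenerational pedigrees are rejected rather than split
  into nuclear units.
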