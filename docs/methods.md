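# Methods

This note documents the models and procedures implemented in melonprint,
the parameter defaults and why they were chosen, the assumptions of the
synthetic-data generator, and the package's numerical conventions and known
limitations.

## Perfect-marker screening

A *perfect* marker is one a short amplicon can genotype robustly: its site
and both flanks are free of confounding variation and map uniquely.

**SSR scanning.** For each motif length k = 2…6 the scanner locates maximal
period-k intervals (every base equals the base k positions earlier); an
interval of length L anchored at its left end yields a tract of ⌊L/k⌋ full
motif copies. Tracts are discarded when the motif is not primitive (a
shorter-unit repeat in disguise, e.g. ATAT is the dimer AT), when the copy
number is below the per-motif-length minimum, when the tract reaches 50 bp,
or when it contains N. Motifs are reported as the lexicographically
smallest rotation on the given strand; reverse-complement motifs are kept
distinct (strand collapsing is not applied, as amplicon design is
strand-specific). Overlaps between tracts of different periods are resolved
longest-first, then leftmost. Minimum copy numbers default to 5 for
dimers, 4 for trimers and 3 for 4–6-mers — conventional microsatellite
mining settings; they are configurable because panel sizes are sensitive to
them.

**Perfect-SSR screen.** A tract passes iff (i) no SNP or indel from the
variant catalog and no other SSR tract intersects the tract or its 50-bp
flanks, and (ii) every accession's major SSR allele read frequency exceeds
0.7. The read-frequency evidence is consumed as a precomputed per-accession
table; extracting it from raw reads is upstream of this package's inputs.
An accession with no reads (NaN/absent entry) fails the screen
(`no_coverage`). A tract whose full 50-bp flank runs off the contig fails
rather than being evaluated on a shrunken window.

**Perfect-SNP screen.** A biallelic candidate passes iff missing rate
< 0.1, heterozygosity < 0.1 (computed per locus across accessions), MAF
> 0.05, no other catalog variant within ±50 bp, and the ±50-bp window
around the site — with the focal base masked — occurs exactly once in the
genome counting both strands. Uniqueness is an exact full-window occurrence
count rather than an alignment-based mappability score: it is
deterministic, dependency-free, and directly checkable by a naive scan.
Multi-allelic records fail outright. VCF records with FILTER other than
PASS still count as variation in a flank by default (a failed call is still
evidence of instability); this is configurable.

Coordinates are 1-based inclusive throughout the discovery module.

## Genotype matrix and diversity statistics

The central object is a varieties × loci matrix of unordered diploid
genotypes: SSR alleles are integer repeat numbers, SNP alleles bases.
Cells are fully observed or fully missing; missing cells are excluded from
the numerator and denominator of every statistic and are never imputed.
Capillary-electrophoresis fragment sizes are converted to repeat numbers
with `fragment_size_to_repeats`: (size − offset)/motif length, rounded to
the nearest integer, with a configurable per-locus offset for the
non-repeat part of the amplicon.

PIC is computed as gene diversity, PIC = 1 − Σpᵢ². This form caps
biallelic loci at 0.50, matching how SNP informativeness is conventionally
reported for fingerprinting panels; the Botstein form
(1 − Σpᵢ² − ΣΣ 2pᵢ²pⱼ², biallelic cap 0.375) is provided as
`pic_botstein` for comparison.

QC removes loci with PIC < 0.1 or missing rate > 0.20. These thresholds
are package defaults (configurable); they reproduce the intent of dropping
uninformative and unreliable loci before panel analysis.

## Variety identification

For each variety pair, a locus contributes one difference iff both
genotypes are observed and their unordered allele pairs differ; (A,T)
equals (T,A), and (A,A) differs from (A,T). Loci missing in either member
are excluded from the pair's compared-locus count. Percent differences are
computed against the *total* panel size (fixed denominator), so pairs with
missing data are conservatively pulled toward zero; both the difference and
compared-locus matrices are reported so callers can renormalize.
Histogram bins are half-open [lo, hi) with the last bin closed, 10% wide by
default. SSR/SNP concordance is ordinary least squares on the vectorized
strict upper triangles, with R² the squared Pearson correlation; a constant
axis is reported as R² = 0.

## Core marker sets

Selecting the smallest marker subset under which every variety is unique is
minimum test-set cover (NP-hard), so the workhorse is greedy forward
selection: at each step take the marker resolving the most currently
unresolved pairs. A pair with a missing call at a marker is *not* resolved
by it — certification caution. Ties break by higher PIC, then lower
missing rate, then panel order, making selection deterministic.
`exhaustive_core_set` enumerates subsets in increasing size (capped at 15
markers) as a verification oracle; tests confirm the greedy result is never
smaller than the optimum and stays within the (1 + ln #pairs) set-cover
bound. Resolution is reported both pair-wise (resolved pairs / all pairs)
and variety-wise (varieties distinguishable from *every* other variety);
"differentiates 99% of varieties" is interpreted as the variety-wise rate,
with the pair rate also reported.

## Population genetics

**Bruvo distance.** Per allele pair d(x, y) = 1 − 2^−|x−y| in repeat
units; the locus distance is the minimum over the two perfect matchings of
the mean per-pair distance, and the pair distance is the mean over loci
observed in both varieties. SNP loci enter the same formula with alleles
one "step" apart, contributing 0, 0.25, 0.5 per locus (shared homozygote /
one mismatching allele / alternatively homozygous under best pairing),
which keeps a single distance on [0, 1] across marker types. Bruvo's
genome-addition/loss models for mixed ploidy are not implemented — the
package is diploid-only.

**Neighbor joining.** Canonical Q-criterion agglomeration. Ties in Q break
to the smallest node-creation-index pair; negative branch lengths are
clamped to zero with the deficit moved to the sister branch, preserving the
joined pair's path length. Both rules exist purely for determinism. Tests
verify exact recovery of random additive 6-leaf trees and cross-check
patristic distances through dendropy's newick parser.

**AMOVA.** Three strata: among populations, among individuals within
populations, within individuals. Per locus, sums of squared deviations are
computed from allele-level mismatch distances (0/1) using the standard
identities (total SSD = (N² − Σc²)/2N for allele counts c), summed over
loci. Degrees of freedom are k − 1, n − k, n. Variance components follow
the nested-design expected mean squares with the unbalanced coefficient
n_c = (N − ΣN_p²/N)/(k − 1) computed on allele counts. Percentages are
components over their total; negative components are reported and flagged
rather than truncated. Φ_ST, Φ_IS and Φ_IT accompany the table. The
mismatch metric is the choice most faithful to genotype-call data; a
Euclidean-on-allele-counts variant was considered and rejected as adding a
second convention without changing the synthetic benchmark's conclusions.
Admixed (or unlabelled) varieties are excluded, as are singleton
populations (with a warning).

**F_ST.** The pairwise table uses the multiallelic Weir–Cockerham θ,
accumulated as a ratio of sums of the a/b/c components over alleles and
loci. θ was preferred over AMOVA-Φ for the pairwise table because it is
the field-standard estimator for allele-frequency differentiation; both
routes are exposed. Tests verify parameter recovery (±0.05) from
Balding–Nichols simulations at F ∈ {0.1, 0.3, 0.55}.

**Membership labelling.** A variety is assigned its argmax population when
the coefficient is ≥ 0.70, else "admixed"; the boundary value 0.70 counts
as assigned.

## SNP-index scans and diagnostic markers

The SNP-index of a population at a SNP is its reference-allele frequency
over non-missing allele draws — computed from genotype calls, not read
counts, because read depths are upstream of this package's inputs.
Sliding windows are [start, start + 100 kb) advancing by 10 kb from
position 1, truncated at the chromosome end; window means are unweighted
over contained SNPs, and empty windows carry NaN rather than 0. The
ΔSNP-index is the absolute between-population difference — only the
absolute difference makes "Δ = 1" mean alternatively fixed alleles.
`fixed_differences` additionally requires ≥ 10 observed allele draws per
population (a fixation claim needs evidence). Diagnostic genotypes default
to the homozygous population-specific allele; heterozygotes do not count
as carriers, and multi-marker combinations are AND-ed.

## Synthetic-data generator

The generator emulates the structure of a commercial melon variety panel;
its defaults are the study conditions under which everything is tested:

- 125 + 103 pure varieties in two subpopulations plus 31 admixed hybrids
  (259 total); 129 SSR + 159 SNP loci on 12 chromosomes.
- Divergence: Balding–Nichols. Each locus draws an ancestral frequency;
  subpopulation frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F) draws
  (Dirichlet analogue over the SSR allele ladder) with F = 0.55, the
  between-subspecies differentiation regime.
- Inbreeding: genotypes are homozygous single draws with probability
  s = 0.85, else Hardy–Weinberg draws, yielding the mostly-homozygous
  varieties typical of inbred cultivars.
- Admixture: hybrid varieties draw from q·p₁ + (1−q)·p₂ with
  q ~ U(0.35, 0.65), recorded in the Q table, so they fall below the 70%
  membership threshold by construction.
- SSR loci carry 2–15 alleles (2 + Poisson(3.3), capped; ladder mean
  ≈ 5.3) as consecutive repeat numbers. Observed allele counts are lower
  than the ladder mean because drift fixes some alleles within
  subpopulations.
- Missing rates are locus-specific: max · Beta(1.2, 8) with max 0.29 for
  SSRs and 0.06 for SNPs — most loci genotype nearly completely, a tail
  reaches the maximum.
- Ascertainment: panel markers were screened to segregate (the MAF > 0.05
  rule), so non-diagnostic SNP frequencies are clipped away from fixation
  (0.02) and redrawn until the pooled MAF is ≥ 0.08, and SSR draws are
  redrawn until at least two alleles stay common. Without this, drift at
  F = 0.55 would fix loci alternatively by chance and blur the planted
  diagnostic signal — real panels were ascertained the same way.
- Two planted diagnostic SNPs are forced reference-fixed in pop1 and
  alternative-fixed in pop2, with no missing calls (they emulate validated
  assay markers). Admixed hybrids draw these loci from their mixture
  frequencies and may legitimately carry either allele; diagnostic
  sensitivity/specificity are therefore defined over the labelled
  subspecies members, as subspecies diagnosis is undefined for hybrids.

The generator is deterministic: equal configuration (including seed) gives
byte-identical outputs.

What the synthetic benchmark does *not* show: linkage disequilibrium and
recombination structure (loci are independent), stepwise SSR mutation
dynamics (frequencies are Dirichlet draws over a ladder, not a coalescent),
genotyping-error processes beyond missingness, and the near-duplicate
pedigree structure of real commercial panels (which is what pushes real
core sets up to tens of markers; synthetic core sets are smaller).
Passing tests demonstrate correctness of the statistics and the internal
consistency of the pipeline, not field performance of any particular panel.

A separate toy-genome generator plants SSR tracts (clean and
flank-contaminated), SNPs violating each screening criterion, and a
segmental duplication that defeats flank uniqueness, and emits the
ground-truth manifest used as the discovery-stage oracle. Its backbone
sequence is regenerated until repeat-free so planted tracts are the only
tracts, and planted tract boundaries are sealed with periodicity-breaking
spacer bases so scanned coordinates equal planted coordinates exactly.

## Problem sizes and determinism

The default test suite and the acceptance script run entirely on generated
data: the 259-variety panel (seconds per full pipeline), 100 random 5-kb
sequences for the scanner/oracle equivalence, 50 random 8×12 instances for
greedy-vs-exhaustive core sets, 200 loci × 400 samples per F value for
F_ST recovery, and 50 random 6-leaf trees for NJ. These sizes were chosen
as the smallest at which each property is sharply testable. All
randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

- Diploid genotypes only; no phasing, imputation, or polyploidy.
- AMOVA degrees of freedom use the full sample size even when individual
  loci have missing calls (locus-wise complete-case SSDs are summed);
  with locus-specific missingness the df are therefore nominal.
- The flank-uniqueness check is exact-match only; it does not model
  near-identical paralogs that would still cross-amplify.
- STRUCTURE-style admixture inference is out of scope: Q matrices are
  consumed, not estimated.
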