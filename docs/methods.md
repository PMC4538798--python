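# Methods

## Scope and data model

The package analyses somatic variation in tumor/normal pairs from
early-stage high-grade serous ovarian carcinoma at desk scale.  Inputs
are post-calling artifacts — somatic variant calls with read support
(VCF, or a lossless TSV dialect), copy-number/LOH segment tables (SEG
with an LOH column), SV breakpoint pairs (BEDPE), gene/exon intervals
(BED) and per-sample purity/ploidy — never reads or alignments.
Variant positions are 1-based (VCF convention); segments and gene
intervals are 0-based half-open (BED convention); all conversions live in
`ovatime.core`.  Functional annotation categories are a fixed
13-term vocabulary (missense, nonsense, splice site, silent, UTRs,
flanks, intron, intergenic, de-novo-start in-frame, frameshift
insertion/deletion); unknown categories are rejected rather than
coerced so category tabulations stay auditable.  Multi-allelic VCF
records are split into biallelic records on read.

## Somatic filter battery

SNVs pass when all of the following hold: somatic score ≥ 15; not a
catalogued dbSNP variant with minor allele frequency ≥ 1% (unflagged
sites pass regardless); at least 2 mutant reads with base quality ≥ Q20;
mutant reads on both strands; Fisher strand bias ≤ 40 (equality passes);
germline mutant reads ≤ max(1, ⌊1% of germline coverage⌋); at most 2
highly homologous regions around the site (a precomputed annotation —
recomputing homology from a reference is out of scope).  The floor in
the germline allowance makes the allowance an attainable read count; the
homology bound treats "no more than two" as count ≤ 2 passing.  Indels
face the same battery minus the base-quality and strand-bias rules,
which their caller does not report.  Every rule is evaluated
independently and a verdict lists all failed rules, which makes the
battery monotone: relaxing one threshold can never shrink the pass set.
A missing field needed by an enabled rule is an error, never a silent
pass.

## Mutation spectrum

Substitutions are folded to the pyrimidine strand (six classes C>A, C>G,
C>T, T>A, T>C, T>G); transitions are C>T and T>C; the CpG flag marks a
pyrimidine-strand C immediately followed by G.  Context-normalized rates
divide counts by the number of genomic contexts at which each mutation
type can occur, separately for exonic and non-exonic strata, with C>T
further split by CpG status.  For synthetic genomes, which carry no
literal sequence, opportunities derive from an assumed composition
(GC fraction 0.42; CpG-C fraction of C's 0.08 in exons, 0.02 elsewhere —
CpG-richer exons reflect hypomethylation-driven CpG depletion outside
genes).  The exonic-vs-non-exonic rate comparison uses per-sample rates
(count / stratum footprint) and a two-sided paired t-test coded from the
closed form (mean and SD of paired differences, n−1 df) so small-n
behaviour is explicit; it matches `scipy.stats.ttest_rel` and is
cross-checked against it.  The non-synonymous set for the NS/S ratio is
{missense, nonsense, splice site} over {silent}; samples with zero
silent mutations are excluded from the cross-sample mean.  Because the
category set behind published NS/S figures is not standardized, that
printed ratio is reported but not treated as a reproduction target.

## Gene-level burden

Per-gene density is (indels + SNVs) × 10⁶ / covered bases, reported to
two decimals; covered bases are inputs.  The enrichment p-value is an
upper-tail Poisson test per variant class with mean = genome-wide class
rate × covered bases, combined across the two classes by Fisher's
method (−2 Σ ln p ~ χ², 4 df).  This is a deliberate simplification of
full coverage-aware SMG machinery (per-sample coverage modelling,
convolution tests); it is monotone in the observed count at fixed
exposure and conservative under the null (verified by simulation at 10⁴
genes), and only the density column — not the p-value column — is used
when reproducing published tables.  A configurable blacklist (empty by
default) drops gene-family/highly polymorphic genes.

## Kataegis

A mappability pre-filter removes variants whose flanking-window
mapping-location count (a precomputed annotation) exceeds 3.  Rainfall
distances are computed per chromosome within a sample — chromosome
boundaries never produce a distance — and duplicate positions yield
distance 0.  Candidate calls are maximal runs of consecutive mutations
whose mean inter-mutation spacing stays ≤ 1 kb, with ≥ 6 members; both
thresholds are configurable.  The run rule is a numeric stand-in for
what is usually judged visually from rainfall plots: the ≥ 6 / ≤ 1 kb
convention is the field's standard.  The scan is greedy left-to-right
(extend while the running mean stays under threshold), deterministic,
idempotent, and verified against an independently coded brute-force
scan.  Chromosome-scale hypermutation of one substitution type (e.g. a
T>C-saturated chromosome) is a different phenomenon from cluster-scale
kataegis and is screened separately: a per-chromosome binomial test of
the type's fraction against the genome-wide fraction.

## HRD and LOH

The HRD score counts LOH regions strictly longer than 15 Mb after
merging adjacent LOH segments separated by < 1 kb — merging makes the
score invariant to arbitrary segmentation splits (property-tested).
The HRD-like score applies the same counting to copy-number-decrease
segments (log2 ≤ −0.3, the deletion-eligibility cutoff used by the
timing stage; the literature states no specific cutoff for this variant
score, so it is exposed as a flag).  LOH burden is LOH bases over the
assayed genome.  Classification: HRD-high at score ≥ 15 (the boundary
is inclusive — with the printed cohort scores only ≥ reproduces the
published 10-of-16 split, since one sample scores exactly 15, while the
length rule for counting regions stays strictly > 15 Mb);
tetraploid-like at mean ploidy > 3.5; low-LOH at burden < 0.10.
Whole-chromosome LOH exclusion is available but off by default.  The
cohort occurrence table counts, per fixed genomic bin, samples with any
LOH overlap.

## Timing estimator

The expected mutant allele frequency of an SNV on a hemizygous-deletion
segment is m = x·c·f / (2·(1 − c·x) + x·c): purity x, deletion-clone
fraction c, mutated fraction f of that clone, mutant copies in the
numerator, total copies (2 per non-deleted cell, 1 per deleted cell) in
the denominator.  Timing-informative SNVs lie within 1 Mb of the gene
span and need ≥ 15 tumor reads, zero germline mutant reads, no dbSNP
overlap and germline coverage ≥ 10; MMAF is their weighted mean allele
fraction with weights 1 − 2^(−g) (an undetected germline heterozygote
yields zero variant reads in g reads with probability 2^(−g)).  The
deleted-cell fraction comes either directly (cna = c·x when truth is
known) or from segment data: the mean log2 over the segments under the
selected SNVs (averaged before correction), divided by purity, then
inverted under the hemizygous model cna = 2·(1 − 2^L′), clamped to
[0, 1].  The log2-division purity correction is the conventional
approximation and is exact only at x = 1; recovery tests therefore
use the direct (m, cna) route, and the data route is regression-tested
at x = 1.

Per observation f_i = m_i·(2 − cna_i)/cna_i, the exact algebraic inverse
of the model, so noise-free pairs generated at known f recover it to
machine precision.  An alternative printed form of the estimator,
f_i = (m_i − cna_i)·2(1 − cna_i)/cna_i, is preserved behind
`method="paper-verbatim"` for comparison; it is not the model inverse
(it does not return 1 when m is generated with f = 1) and is not the
default.  F is the mean of f_i; the confidence range is the min/max of
the n leave-one-out means; significance of F < 1 is a one-sided
Wilcoxon signed-rank test on f_i − 1.  With binomial read noise the
estimator is unbiased in m and hence in F; at depth 100 and n = 50
regions, |bias| < 0.05 and RMSE < 0.08 over 500 replicates (recomputed
by the acceptance script).  Restricting MMAF to deleterious annotation
categories (nonsense, splice, frameshift) is a policy flag, mirroring
deleterious-only gene contrasts.

## Wilcoxon signed-rank test

Implemented in-package because the exactness requirement extends to tied
|differences|, which scipy's exact mode refuses.  Zeros are dropped;
for effective n ≤ 25 the null distribution of the positive-rank sum is
computed exactly, conditional on the observed midranks, by a
generating-function convolution over doubled ranks (doubling makes
midranks integral) — equivalent to enumerating all 2ⁿ sign assignments,
and tested against that enumeration and against scipy on tie-free
inputs.  Above n = 25 a normal approximation with tie-corrected
variance (Σ rᵢ²/4) and continuity correction is used.  Type-I error at
α = 0.05 under a symmetric null is ≤ 0.06 (10⁴ replicates).

## SV deduplication and clustering

Two SVs are duplicates when both corresponding breakpoints are on
matching chromosomes within 10 bp; duplicate groups are transitive
closures resolved to the first member in canonical sorted order, making
deduplication permutation-invariant.  Clustering links unique SVs when
any breakpoint of one lies within 1 Mb of any breakpoint of the other on
the same chromosome; clusters are connected components (union-find);
singletons are unclustered; interchromosomal events participate through
each breakpoint independently.  Component closure is used because the
relation of interest is membership in a breakage neighbourhood, not
pairwise proximity alone.

## Cohort copy-number comparison

A sample is altered in a region when segments meeting the log2 cutoff in
the stated direction cover ≥ 50% of the region (the overlap rule is a
package choice, exposed as a flag, and split-invariant).  Early-cohort
alteration counts are tested against the late-stage frequency with an
exact two-sided binomial test (minimum-likelihood sidedness); per-sample
mean log2 over a region uses Welch's t; CN–expression association uses
Spearman correlation with average-rank ties, exact permutation p for
n ≤ 9, t-approximation above.  "Consistent and significant" across
several early cohorts is implemented as: every test significant at α and
all effects sharing one sign.

## Synthetic tumor generator

The generator emulates the statistical structure the stages assume, not
reads: a diploid mini-genome (default three 50 Mb chromosomes) with
non-overlapping hemizygous deletions (exponential lengths, mean 8 Mb,
min 1 Mb) assigned a clone fraction; SNVs placed with a 2× non-exonic
vs exonic rate contrast over ~3% exonic footprint; substitution types
drawn from a 12-type categorical whose defaults reproduce the study
cohort's printed spectrum shape (C>T most common at 27%, T>G rarest at
8%, transitions 55% overall so every chromosome shows Ts > Tv); CpG
status for C>T drawn with a 3× enrichment confined to exonic regions,
mirroring the exon-restricted CpG effect; read counts binomial at the
model-expected MAF (deletion sites use the timing model with f = 1
before-deletion or a configurable f after; off-deletion sites use x/2)
at fixed mean depth 46 in tumor and normal (the study's mean coverage),
with Poisson-varying depth as a flag; purity defaults to 0.6, a
mid-range specimen purity (per-sample purity estimates were not printed,
so one realistic value was fixed).  Heterozygous germline sites are
emitted with tumor B-allele frequency (1 − cna)/(2 − cna) under LOH and
0.5 otherwise.  Segment log2 ratios get Gaussian noise (SD 0.05), a
generator choice since no log2 noise model is stated anywhere.
Kataegis clusters are spiked with capped-exponential spacing (mean
200 bp, cap 10×) and a fixed substitution type (default T>C); SV sets
are planted on a 4 Mb slot grid so that exactly round(target·n) SVs are
1 Mb-clustered (groups of 2–3 share a slot; distinct slots are > 2 Mb
apart), making the planted clustered fraction recoverable exactly.  All
randomness flows through one numpy Generator seeded from the config;
identical seeds reproduce identical outputs.

What the generator does *not* emulate — mapping artifacts, sequence
context at literal base resolution, subclonal phylogenies deeper than
one clone per event, GC-coverage bias, contamination — bounds what
passing tests show: they validate the estimators under the stated
noise model, not robustness to real-data artifacts.

## Problem sizes and numerics

Tests and the acceptance script run on the 3×50 Mb mini-genome with
cohorts of 15–16 samples, 300–1000 SNVs per sample and depths 46–100;
recovery statistics use 500 replicates (timing) and 10⁴ replicates
(Wilcoxon calibration) — sizes chosen so the whole suite runs in well
under a minute while keeping Monte-Carlo error far from the asserted
bounds.  On a genome 5% the size of a human genome the HRD score of a
typical synthetic sample is 0–2, so synthetic cohorts mostly classify
HRD-low; published-scale classification is exercised on the printed
cohort score table instead.  Published summary tables (per-patient
category counts, per-gene mutation cells, per-sample HRD scores and
burdens) ship inside the package as inputs for that arithmetic.  Ties
at the Wilcoxon shift point are dropped before ranking; degenerate
cases (zero variance in paired tests, constant vectors in Spearman,
zero opportunities, zero-weight MMAF) return defined missing values or
raise typed errors rather than propagating NaNs silently.
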