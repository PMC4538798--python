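# ovatime

Desk-scale somatic-genome analyses for early-stage high-grade serous
ovarian carcinoma (HGSOC).  The package re-implements, as a tested
pipeline over synthetic tumor/normal data, the bespoke computational
stages of a whole-genome tumor/normal study: somatic variant filtering,
mutation-spectrum statistics, significantly-mutated-gene scoring,
kataegis (rainfall) detection, HRD/LOH scoring, structural-variant
clustering, cross-cohort copy-number comparison — and, at its core, the
temporal-ordering estimator that asks whether somatic point mutations in
a region predate or postdate the hemizygous deletion that removed the
other allele.

It is aimed at cancer-genomics methodologists who want every one of these
stages runnable, inspectable and testable on a laptop: a synthetic
tumor-genome generator provides cohorts with known purity, clone
fractions, mutation timing, LOH structure, kataegis clusters and SV
clusters, so each stage can be validated against ground truth rather
than against irreproducible raw reads.

## The timing model

For a hemizygous deletion carried by a clone occupying fraction *c* of
the cancer cells in a specimen of purity *x*, an SNV carried by a
fraction *f* of that clone (on the retained allele) has expected mutant
allele frequency

    m = x·c·f / (2·(1 − c·x) + 1·x·c)

— mutant copies over total copies, with 2 copies per non-deleted cell and
1 per deleted cell.  Writing cna = c·x (the fraction of *all* cells
carrying the deletion, obtained from the purity-corrected segment log2
ratio), the estimator inverts the model per observation,

    f_i = m_i · (2 − cna_i) / cna_i ,       F = ⟨f_i⟩ ,

with a leave-one-out range for F and a one-sided exact Wilcoxon
signed-rank test of f_i − 1 < 0.  F ≈ 1 means the region's mutations
preceded the deletion; F < 1 means a fraction arose after it.  The MMAF
m is a weighted mean of SNV allele fractions, each SNV weighted by
1 − 2^(−g) (the confidence, given g clean germline reads, that the site
is not an undetected germline heterozygote).

Other quantities follow the field's standard definitions: the HRD score
counts LOH regions longer than 15 Mb; LOH burden is the LOH fraction of
the assayed genome; kataegis candidates are runs of ≥ 6 mutations with
mean inter-mutation spacing ≤ 1 kb on a per-chromosome rainfall;
SVs with both breakpoints within 10 bp are duplicates, and unique SVs
within 1 Mb of each other form clusters (connected components).

## Worked example

```python
import dataclasses
from ovatime.simulate import SimConfig, generate_dataset, simulate_timing_pairs
from ovatime.timing import estimate_f
import numpy as np

# a tumor at purity 0.6 where half the deletion clone mutated after the event
rng = np.random.default_rng(1)
pairs = simulate_timing_pairs(n_regions=7, depth=46, purity=0.6,
                              clone_fraction=1.0, f_true=0.5, rng=rng,
                              snvs_per_region=5)
est = estimate_f(pairs)
print(f"F = {est.F:.3f}, LOO range {est.loo_range}, p = {est.p_wilcoxon:.4f}")
```

prints

```
F = 0.497, LOO range (0.4876843764144006, 0.5064993516088246), p = 0.0078
```

F recovers the planted clone fraction 0.5; the Wilcoxon p-value 0.0078
(= 2⁻⁷, all seven f_i below 1) rejects "mutations first" at n = 7
regions, whereas the same simulation with `f_true=1.0` yields F ≈ 1 and a
non-significant p.  The numbered scripts under `analysis/` run the same
machinery cohort-wide: `01_simulate_cohort.py` writes a 16-sample
synthetic cohort (VCF/SEG/BEDPE plus ground truth) under
`results/cohort/`, and scripts 02–09 filter it, tabulate its spectrum,
score genes, call kataegis, score HRD/LOH, estimate timing, cluster SVs
and compare copy-number cohorts, each printing a short summary and
writing TSVs under `results/`.

A thin CLI mirrors the same stages
(`ovatime simulate|filter|spectrum|smg|kataegis|hrd|timing|svcluster|compare`);
run `ovatime --help`.

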