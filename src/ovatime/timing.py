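"""Temporal ordering of somatic mutations relative to hemizygous deletions.

The model: a hemizygous deletion carried by a clone occupying fraction
``c`` of the cancer cells, in a specimen of purity ``x``, leaves a mutant
allele frequency

    m = x*c*f / (2*(1 - c*x) + 1*x*c)

for an SNV carried by a fraction ``f`` of the deletion clone (f = 1 when
every mutation preceded the deletion and sits on the retained allele).
Writing ``cna = c*x`` (the fraction of *all* cells carrying the deletion),
the exact inverse is ``f = m*(2 - cna)/cna``.  The cohort estimator ``F``
is the mean of per-observation ``f_i`` with a leave-one-out range and a
one-sided Wilcoxon signed-rank test of the alternative ``f_i < 1``:
F near 1 means mutations preceded the deletions; F < 1 means some arose
after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GeneModel, Segment, ValidationError, VariantCall
from .stats import wilcoxon_signed_rank_less

__all__ = [
    "TimingPair",
    "TimingSnvPolicy",
    "FEstimate",
    "select_timing_snvs",
    "snp_weight",
    "compute_mmaf",
    "purity_corrected_cna",
    "expected_maf",
    "estimate_f",
    "wilcoxon_less_than_one",
    "timing_pair_from_data",
]

#: Annotation categories treated as deleterious for deleterious-only mode.
DELETERIOUS_CATEGORIES = ("Nonsense", "Splice site", "Frame shift del", "Frame shift ins")


@dataclass(frozen=True)
class TimingSnvPolicy:
    """Eligibility rules for timing-informative SNVs.

    Defaults: >= 15 tumor reads (accurate frequency), no germline mutant
    reads, not a catalogued dbSNP site, germline coverage >= 10, region
    half-width 1 Mb around the gene span, and deletion eligibility at
    log2 ratio <= -0.3.
    """

    min_tumor_depth: int = 15
    max_germline_alt: int = 0
    exclude_dbsnp: bool = True
    min_germline_depth: int = 10
    region_half_width: int = 1_000_000
    deletion_log2_cutoff: float = -0.3
    deleterious_only: bool = False

    def __post_init__(self) -> None:
        for name in ("min_tumor_depth", "max_germline_alt", "min_germline_depth",
                     "region_half_width"):
            if getattr(self, name) < 0:
                raise ValidationError(f"policy threshold {name} must be non-negative")


@dataclass
class TimingPair:
    """One (gene region, sample) observation for the F estimator."""

    sample_id: str
    region: str
    m: float
    cna: float
    n_snvs: int = 1
    clone_fraction: float | None = None
    purity: float | None = None

    def validate(self) -> "TimingPair":
        if not 0.0 <= self.m <= 1.0:
            raise ValidationError(f"{self.sample_id}/{self.region}: m={self.m} outside [0, 1]")
        if not 0.0 < self.cna <= 1.0:
            raise ValidationError(f"{self.sample_id}/{self.region}: cna={self.cna} outside (0, 1]")
        return self


@dataclass
class FEstimate:
    F: float
    loo_range: tuple[float, float] | None
    f_values: tuple[float, ...]
    n: int
    p_wilcoxon: float | None
    note: str = ""


def select_timing_snvs(
    variants: Sequence[VariantCall],
    gene: GeneModel,
    policy: TimingSnvPolicy = TimingSnvPolicy(),
) -> list[VariantCall]:
    """SNVs within the gene span +/- the policy half-width passing all rules."""
    chrom, start, end = gene.span()
    lo = max(0, start - policy.region_half_width)
    hi = end + policy.region_half_width
    selected = []
    for v in variants:
        if v.variant_class != "SNV" or v.chrom != chrom:
            continue
        if not (lo < v.position <= hi):
            continue
        if v.tumor_depth < policy.min_tumor_depth:
            continue
        if v.germline_alt > policy.max_germline_alt:
            continue
        if policy.exclude_dbsnp and v.dbsnp_maf is not None:
            continue
        if v.germline_depth < policy.min_germline_depth:
            continue
        if policy.deleterious_only and v.category not in DELETERIOUS_CATEGORIES:
            continue
        selected.append(v)
    return selected


def snp_weight(germline_depth: int) -> float:
    """Confidence that a site is truly somatic given clean germline coverage.

    An undetected heterozygous germline variant would produce zero variant
    reads among g germline reads with probability 2^(-g); the weight is
    one minus that, so zero coverage gives weight 0 (uninformative) and
    deep clean coverage approaches 1.
    """
    if germline_depth < 0:
        raise ValidationError("germline depth must be non-negative")
    return 1.0 - 2.0 ** (-germline_depth)


def compute_mmaf(variants: Sequence[VariantCall]) -> tuple[float, int]:
    """Weighted mean mutant allele frequency over selected SNVs.

    Weights come from :func:`snp_weight` on germline coverage.  Raises when
    no variant is supplied or all weights are zero.
    """
    if not variants:
        raise ValidationError("MMAF undefined: no selected variants")
    weights = np.array([snp_weight(v.germline_depth) for v in variants])
    freqs = np.array([v.tumor_vaf for v in variants])
    total = weights.sum()
    if total == 0.0:
        raise ValidationError("MMAF undefined: all SNP weights are zero")
    return float((weights * freqs).sum() / total), len(variants)


def purity_corrected_cna(log2_ratio: float, purity: float) -> float:
    """Deleted-cell fraction from a segment log2 ratio and tumor purity.

    The log2 ratio is first divided by purity (correcting attenuation from
    admixed normal cells), then inverted under the hemizygous-deletion
    model: a deletion in fraction ``cna`` of cells gives mixture copy
    number 2 - cna, hence ratio 2^(L') = 1 - cna/2 and
    cna = 2*(1 - 2^(L')), clamped to [0, 1].
    """
    if purity <= 0 or purity > 1:
        raise ValidationError(f"purity {purity} outside (0, 1]")
    corrected = log2_ratio / purity
    return float(min(1.0, max(0.0, 2.0 * (1.0 - 2.0**corrected))))


def expected_maf(x: float, c: float, f: float) -> float:
    """Expected mutant allele frequency under the hemizygous-deletion model.

    ``m = x*c*f / (2*(1 - c*x) + 1*x*c)``: mutant copies are present in
    the fraction ``c*x*f`` of cells that carry the mutation on the
    retained allele; total copies are 2 per non-deleted cell and 1 per
    deleted cell.
    """
    for name, val in (("x", x), ("c", c), ("f", f)):
        if not 0.0 <= val <= 1.0:
            raise ValidationError(f"{name}={val} outside [0, 1]")
    denom = 2.0 * (1.0 - c * x) + x * c
    return x * c * f / denom


def _invert(m: float, cna: float, method: str) -> float:
    if method == "inversion":
        return m * (2.0 - cna) / cna
    if method == "paper-verbatim":
        # The printed estimator; kept for reproduction attempts even though
        # it is not the algebraic inverse of the expected-MAF model.
        return (m - cna) * (2.0 * (1.0 - cna) / cna)
    raise ValidationError(f"unknown method {method!r}")


def estimate_f(
    pairs: Sequence[TimingPair], method: str = "inversion"
) -> FEstimate:
    """Estimate F = <f_i> over (m, cna) observations.

    Per observation, ``f_i`` inverts the expected-MAF model at the
    observed MMAF and deleted-cell fraction (default exact inversion;
    ``method="paper-verbatim"`` applies the printed alternative).  F is
    the mean of f_i; the confidence range is the (min, max) over the n
    leave-one-out means; significance of F < 1 is the one-sided exact
    Wilcoxon signed-rank p-value on f_i - 1.
    """
    if not pairs:
        raise ValidationError("estimate_f needs at least one pair")
    for p in pairs:
        p.validate()
    f_values = tuple(_invert(p.m, p.cna, method) for p in pairs)
    n = len(f_values)
    F = float(np.mean(f_values))
    if n >= 2:
        arr = np.asarray(f_values)
        loo = (arr.sum() - arr) / (n - 1)
        loo_range: tuple[float, float] | None = (float(loo.min()), float(loo.max()))
        p_value: float | None = wilcoxon_less_than_one(f_values)
        note = ""
    else:
        loo_range = None
        p_value = None
        note = "n = 1: leave-one-out range and Wilcoxon p unavailable"
    return FEstimate(F=F, loo_range=loo_range, f_values=f_values, n=n,
                     p_wilcoxon=p_value, note=note)


def wilcoxon_less_than_one(f_values: Sequence[float]) -> float:
    """One-sided exact Wilcoxon signed-rank p for median(f) < 1.

    Values exactly 1 are dropped (signed-rank zero handling); with no
    remaining values the p-value is 1.
    """
    p, _n = wilcoxon_signed_rank_less(f_values, mu=1.0)
    return p


def timing_pair_from_data(
    sample_id: str,
    gene: GeneModel,
    variants: Sequence[VariantCall],
    segments: Sequence[Segment],
    purity: float,
    policy: TimingSnvPolicy = TimingSnvPolicy(),
) -> TimingPair | None:
    """Build one (gene, sample) timing observation from raw inputs.

    Selects eligible SNVs around the gene, averages the log2 ratio of the
    segment under each selected SNV (mean of per-SNV segment log2 first,
    purity correction second), and requires deletion eligibility: mean
    log2 <= the policy cutoff.  Returns ``None`` when no eligible SNV or
    no eligible deletion.
    """
    selected = select_timing_snvs(variants, gene, policy)
    if not selected:
        return None
    sample_segments = [s for s in segments if s.sample_id in ("", sample_id)]
    log2s = []
    for v in selected:
        for seg in sample_segments:
            if seg.chrom == v.chrom and seg.contains(v.position):
                log2s.append(seg.log2)
                break
    if not log2s:
        return None
    mean_log2 = float(np.mean(log2s))
    if mean_log2 > policy.deletion_log2_cutoff:
        return None
    cna = purity_corrected_cna(mean_log2, purity)
    if cna <= 0.0:
        return None
    m, n_snvs = compute_mmaf(selected)
    return TimingPair(
        sample_id=sample_id, region=gene.name, m=m, cna=cna, n_snvs=n_snvs, purity=purity
    ).validate()
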