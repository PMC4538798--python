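"""Cross-cohort copy-number comparisons and CN-expression correlation.

For a fixed genomic region, a sample is "altered" when segments meeting a
log2 cutoff (loss or gain) cover at least half of the region.  Early-
cohort alteration counts are tested against the late-stage frequency with
an exact two-sided binomial test; per-sample mean log2 ratios over a
region are compared across cohorts with Welch's t-test; copy number vs
expression uses Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Segment, ValidationError
from .stats import binomial_two_sided, spearman, welch_t

__all__ = [
    "RegionFrequency",
    "region_frequency",
    "sample_altered_in_region",
    "mean_log2_over_region",
    "binomial_frequency_test",
    "region_mean_log2_ttest",
    "cn_expression_correlation",
    "consistent_difference",
]

MIN_COVERED_FRACTION = 0.5


@dataclass(frozen=True)
class RegionFrequency:
    region: str
    cohort: str
    altered: int
    size: int
    frequency: float


def _altered_bases(
    segments: Sequence[Segment],
    chrom: str,
    start: int,
    end: int,
    log2_cutoff: float,
    direction: str,
) -> int:
    if direction not in ("loss", "gain"):
        raise ValidationError(f"direction must be 'loss' or 'gain', got {direction!r}")
    bases = 0
    for seg in segments:
        if seg.chrom != chrom:
            continue
        overlap = min(seg.end, end) - max(seg.start, start)
        if overlap <= 0:
            continue
        if (direction == "loss" and seg.log2 <= log2_cutoff) or (
            direction == "gain" and seg.log2 >= log2_cutoff
        ):
            bases += overlap
    return bases


def sample_altered_in_region(
    segments: Sequence[Segment],
    chrom: str,
    start: int,
    end: int,
    log2_cutoff: float,
    direction: str = "loss",
    min_covered_fraction: float = MIN_COVERED_FRACTION,
) -> bool:
    """True when qualifying segments cover >= the required region fraction."""
    if end <= start:
        raise ValidationError("empty region")
    covered = _altered_bases(segments, chrom, start, end, log2_cutoff, direction)
    return covered >= min_covered_fraction * (end - start)


def region_frequency(
    cohort_segments: Mapping[str, Sequence[Segment]],
    region: tuple[str, int, int],
    log2_cutoff: float,
    direction: str = "loss",
    cohort_label: str = "",
    region_label: str = "",
    min_covered_fraction: float = MIN_COVERED_FRACTION,
) -> RegionFrequency:
    """Fraction of cohort samples altered in one region."""
    chrom, start, end = region
    altered = sum(
        sample_altered_in_region(
            segs, chrom, start, end, log2_cutoff, direction, min_covered_fraction
        )
        for segs in cohort_segments.values()
    )
    size = len(cohort_segments)
    if size == 0:
        raise ValidationError("empty cohort")
    return RegionFrequency(
        region=region_label or f"{chrom}:{start}-{end}",
        cohort=cohort_label,
        altered=int(altered),
        size=size,
        frequency=altered / size,
    )


def binomial_frequency_test(early_altered: int, early_n: int, late_frequency: float) -> float:
    """Two-sided exact binomial p of the early count under the late frequency."""
    if not 0.0 <= late_frequency <= 1.0:
        raise ValidationError("late frequency must lie in [0, 1]")
    return binomial_two_sided(early_altered, early_n, late_frequency)


def mean_log2_over_region(
    segments: Sequence[Segment], chrom: str, start: int, end: int
) -> float:
    """Base-weighted mean log2 ratio of one sample's segments over a region."""
    if end <= start:
        raise ValidationError("empty region")
    total = 0
    weighted = 0.0
    for seg in segments:
        if seg.chrom != chrom:
            continue
        overlap = min(seg.end, end) - max(seg.start, start)
        if overlap > 0:
            total += overlap
            weighted += overlap * seg.log2
    return weighted / total if total else float("nan")


def region_mean_log2_ttest(
    early_means: Sequence[float], late_means: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test on per-sample mean log2 ratios."""
    return welch_t(early_means, late_means)


def cn_expression_correlation(
    cn_values: Sequence[float], expression: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation between per-sample CN and expression counts."""
    return spearman(cn_values, expression)


def consistent_difference(
    early_tests: Sequence[tuple[float, float]], alpha: float = 0.05
) -> bool:
    """Conjunction rule over several early-vs-late comparisons.

    ``early_tests`` holds (effect, p) per early cohort (effect = early
    frequency minus late frequency).  The difference counts as consistent
    and significant when every test is significant at ``alpha`` and every
    effect shares one sign.
    """
    if not early_tests:
        return False
    effects = [e for e, _ in early_tests]
    ps = [p for _, p in early_tests]
    same_sign = all(e > 0 for e in effects) or all(e < 0 for e in effects)
    return same_sign and all(p < alpha for p in ps)
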