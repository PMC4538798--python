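"""Post-call somatic variant filter battery.

Each rule is evaluated independently and a verdict lists *all* failed
rules, so relaxing one threshold can never hide a failure of another.
SNVs face the full battery; indels (whose caller reports neither per-read
base quality nor strand bias) skip those two rules by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core import ValidationError, VariantCall

__all__ = [
    "FilterPolicy",
    "FilterVerdict",
    "germline_allowance",
    "apply_snv_filters",
    "passing_variants",
    "SNV_POLICY",
    "INDEL_POLICY",
]


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for the somatic filter battery.

    Defaults are the whole-genome study settings: somatic score >= 15,
    dbSNP MAF >= 1% excluded, >= 2 mutant reads at base quality >= Q20
    with both strands represented, Fisher strand bias <= 40, at most
    ``max(1, 1% of germline coverage)`` germline mutant reads, and at most
    two highly homologous regions around the site.
    """

    min_somatic_score: float = 15.0
    dbsnp_maf_threshold: float = 0.01
    min_mutant_reads: int = 2
    min_mutant_base_quality: int = 20
    require_both_strands: bool = True
    max_strand_bias: float = 40.0
    max_homolog_regions: int = 2
    check_base_quality: bool = True
    check_strand_bias: bool = True

    def __post_init__(self) -> None:
        for name in ("min_somatic_score", "dbsnp_maf_threshold", "min_mutant_reads",
                     "min_mutant_base_quality", "max_strand_bias", "max_homolog_regions"):
            if getattr(self, name) < 0:
                raise ValidationError(f"policy threshold {name} must be non-negative")


#: Default SNV policy — the full battery.
SNV_POLICY = FilterPolicy()

#: Default indel policy — same battery minus base-quality and strand-bias rules.
INDEL_POLICY = FilterPolicy(check_base_quality=False, check_strand_bias=False)


@dataclass
class FilterVerdict:
    variant: VariantCall
    failed_rules: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failed_rules


def germline_allowance(germline_depth: int) -> int:
    """Maximum tolerated germline mutant reads: max(1, floor(1% of coverage))."""
    if germline_depth < 0:
        raise ValidationError("germline depth must be non-negative")
    return max(1, math.floor(0.01 * germline_depth))


def _evaluate(variant: VariantCall, policy: FilterPolicy) -> tuple[str, ...]:
    failed: list[str] = []
    v = variant
    if v.somatic_score < policy.min_somatic_score:
        failed.append("min_somatic_score")
    if v.dbsnp_maf is not None and v.dbsnp_maf >= policy.dbsnp_maf_threshold:
        failed.append("dbsnp_common")
    if policy.check_base_quality:
        # Mutant-read support at the required base quality.
        if len(v.bq_mutant) != v.tumor_alt:
            raise ValidationError(
                f"{v.chrom}:{v.position}: base-quality rule enabled but "
                f"{len(v.bq_mutant)} qualities reported for {v.tumor_alt} mutant reads"
            )
        qualified = sum(1 for q in v.bq_mutant if q >= policy.min_mutant_base_quality)
        if qualified < policy.min_mutant_reads:
            failed.append("min_mutant_reads_q20")
    else:
        if v.tumor_alt < policy.min_mutant_reads:
            failed.append("min_mutant_reads")
    if policy.require_both_strands and (v.alt_forward < 1 or v.alt_reverse < 1):
        failed.append("both_strands")
    if policy.check_strand_bias and v.strand_bias > policy.max_strand_bias:
        failed.append("strand_bias")
    if v.germline_alt > germline_allowance(v.germline_depth):
        failed.append("germline_mutant")
    if v.homolog_count > policy.max_homolog_regions:
        failed.append("homologous_regions")
    return tuple(failed)


def apply_snv_filters(
    variants: Sequence[VariantCall], policy: FilterPolicy = SNV_POLICY
) -> list[FilterVerdict]:
    """Evaluate the full battery for each variant; order preserved."""
    return [FilterVerdict(v, _evaluate(v, policy)) for v in variants]


def passing_variants(
    variants: Sequence[VariantCall], policy: FilterPolicy = SNV_POLICY
) -> list[VariantCall]:
    """The subset of variants passing every rule, in input order."""
    return [verdict.variant for verdict in apply_snv_filters(variants, policy) if verdict.passed]
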