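"""Background mutation rate and significantly-mutated-gene scoring.

Per-gene mutation density (mutations per Mb of covered sequence) plus an
enrichment p-value: an upper-tail Poisson test per variant class (SNV,
indel) against the genome-wide background rate, combined across classes
with Fisher's method.  This is a deliberately simple, auditable scoring —
covered bases per gene are inputs, and no per-sample coverage model is
fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import GeneModel, ValidationError, VariantCall
from .stats import fisher_combine, poisson_upper_tail

__all__ = [
    "BackgroundRate",
    "GeneMutationSummary",
    "mutations_per_mb",
    "estimate_bmr",
    "smg_test",
    "score_genes",
]


@dataclass(frozen=True)
class BackgroundRate:
    """Genome-wide per-base mutation rates by variant class."""

    snv: float
    indel: float

    def __post_init__(self) -> None:
        if self.snv < 0 or self.indel < 0:
            raise ValidationError("background rates must be non-negative")


@dataclass
class GeneMutationSummary:
    gene: str
    indels: int
    snvs: int
    covered_bases: int
    mutations_per_mb: float
    p_value: float


def mutations_per_mb(indels: int, snvs: int, covered_bases: int) -> float:
    """(indels + snvs) per megabase of covered gene sequence."""
    if covered_bases <= 0:
        raise ValidationError("covered bases must be positive")
    if indels < 0 or snvs < 0:
        raise ValidationError("counts must be non-negative")
    return (indels + snvs) * 1e6 / covered_bases


def estimate_bmr(
    snv_count: int, indel_count: int, covered_snv: int, covered_indel: int | None = None
) -> BackgroundRate:
    """Background per-base rates: class mutation count / class covered bases."""
    if covered_indel is None:
        covered_indel = covered_snv
    if covered_snv <= 0 or covered_indel <= 0:
        raise ValidationError("covered bases must be positive")
    return BackgroundRate(snv=snv_count / covered_snv, indel=indel_count / covered_indel)


def smg_test(snvs: int, indels: int, covered_bases: int, bmr: BackgroundRate) -> float:
    """Combined enrichment p-value for one gene.

    Upper-tail Poisson per class with mean = class rate x covered bases,
    combined via Fisher's method (−2 Σ ln p ~ χ² with 4 df).  More observed
    mutations at fixed exposure never increase the combined p.
    """
    if covered_bases <= 0:
        raise ValidationError("covered bases must be positive")
    p_snv = poisson_upper_tail(snvs, bmr.snv * covered_bases)
    p_indel = poisson_upper_tail(indels, bmr.indel * covered_bases)
    return fisher_combine([p_snv, p_indel])


def score_genes(
    variants: Sequence[VariantCall],
    genes: Iterable[GeneModel],
    covered_bases: Mapping[str, int] | None = None,
    total_covered: int | None = None,
    blacklist: Iterable[str] = (),
) -> pd.DataFrame:
    """Score each gene's coding mutation burden against the background rate.

    A variant counts toward a gene when its position falls in the gene's
    covered intervals.  ``covered_bases`` overrides per-gene footprints
    (e.g. published covered-bp figures); ``total_covered`` is the exposure
    for the background rate (defaults to the summed gene footprints).
    ``blacklist`` drops gene-family/highly polymorphic genes from output.
    """
    genes = [g for g in genes if g.name not in set(blacklist)]
    cov = {
        g.name: (covered_bases[g.name] if covered_bases and g.name in covered_bases
                 else g.covered_bases)
        for g in genes
    }
    counts = {g.name: {"SNV": 0, "indel": 0} for g in genes}
    for v in variants:
        for g in genes:
            for chrom, s, e in g.intervals:
                if chrom == v.chrom and s < v.position <= e:
                    counts[g.name][v.variant_class] += 1
                    break
    if total_covered is None:
        total_covered = sum(cov.values())
    total_snv = sum(c["SNV"] for c in counts.values())
    total_indel = sum(c["indel"] for c in counts.values())
    bmr = estimate_bmr(total_snv, total_indel, total_covered)
    rows = []
    for g in genes:
        snv_n, indel_n = counts[g.name]["SNV"], counts[g.name]["indel"]
        rows.append(
            {
                "gene": g.name,
                "indels": indel_n,
                "snvs": snv_n,
                "covered_bases": cov[g.name],
                "mutations_per_mb": round(mutations_per_mb(indel_n, snv_n, cov[g.name]), 2),
                "p_value": smg_test(snv_n, indel_n, cov[g.name], bmr),
            }
        )
    df = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    return df
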