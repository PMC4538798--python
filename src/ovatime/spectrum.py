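"""Mutation tabulation and spectrum statistics.

Covers per-patient annotation-category count tables, pyrimidine-strand
substitution classification, context-normalized substitution rates
(CpG vs non-CpG C>T, exonic vs non-exonic), transition/transversion
summaries per chromosome, exonic vs non-exonic mutation-rate comparison
(paired t-test) and the non-synonymous/synonymous ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_CATEGORIES,
    CODING_CATEGORIES,
    GenomeLayout,
    ValidationError,
    VariantCall,
    merge_intervals,
)
from .stats import paired_t

__all__ = [
    "SUBSTITUTION_TYPES",
    "CategoryCountTable",
    "Opportunities",
    "SpectrumTable",
    "classify_substitution",
    "tabulate_by_annotation",
    "build_spectrum",
    "context_normalized_rates",
    "tstv_by_chromosome",
    "regional_rate_comparison",
    "ns_s_ratio",
]

#: The six pyrimidine-strand substitution classes.
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Categories counted as non-synonymous / synonymous for the NS/S ratio.
NONSYNONYMOUS = ("Missense", "Nonsense", "Splice site")
SYNONYMOUS = ("Silent",)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_substitution(ref: str, alt: str, context: str) -> tuple[str, bool, bool]:
    """Classify a single-base substitution on the pyrimidine strand.

    Returns ``(type label, transition flag, CpG flag)``.  Purine-reference
    substitutions are folded by reverse-complementing (ref, alt, context)
    jointly.  The CpG flag is true when the pyrimidine-strand C is
    immediately followed by G.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if ref == alt:
        raise ValidationError("ref and alt must differ")
    if len(ref) != 1 or len(alt) != 1 or any(b not in _COMPLEMENT for b in ref + alt):
        raise ValidationError(f"not a single-base ACGT substitution: {ref}>{alt}")
    if len(context) != 3 or any(b not in _COMPLEMENT for b in context):
        raise ValidationError(f"context must be a 3-mer over ACGT, got {context!r}")
    if context[1] != ref:
        raise ValidationError(f"context middle base {context[1]} does not match ref {ref}")
    if ref in ("A", "G"):
        ref, alt, context = _COMPLEMENT[ref], _COMPLEMENT[alt], _revcomp(context)
    label = f"{ref}>{alt}"
    transition = label in ("C>T", "T>C")
    cpg = ref == "C" and context[2] == "G"
    return label, transition, cpg


# ---------------------------------------------------------------------------
# Table-1-style category counts
# ---------------------------------------------------------------------------


@dataclass
class CategoryCountTable:
    """Per-sample counts of each (variant class, annotation category).

    ``counts`` is indexed by sample with one column per
    ``"<class>:<category>"`` pair; column order follows the fixed
    annotation vocabulary, SNV block first.
    """

    counts: pd.DataFrame
    positions: dict[str, set[tuple[str, int]]] = field(default_factory=dict)

    def row_total(self, sample: str) -> int:
        return int(self.counts.loc[sample].sum())

    def grand_total(self, exclude: Iterable[str] = ()) -> int:
        keep = [s for s in self.counts.index if s not in set(exclude)]
        return int(self.counts.loc[keep].sum().sum())

    def category_totals(self, exclude: Iterable[str] = ()) -> pd.Series:
        keep = [s for s in self.counts.index if s not in set(exclude)]
        return self.counts.loc[keep].sum()

    def coding_total(self, exclude: Iterable[str] = ()) -> int:
        """Sum over coding/splice categories (both variant classes)."""
        totals = self.category_totals(exclude)
        cols = [c for c in totals.index if c.split(":", 1)[1] in CODING_CATEGORIES]
        return int(totals[cols].sum())

    def noncoding_total(self, exclude: Iterable[str] = ()) -> int:
        totals = self.category_totals(exclude)
        cols = [c for c in totals.index if c.split(":", 1)[1] not in CODING_CATEGORIES]
        return int(totals[cols].sum())

    def deduplicated_total(self, exclude: Iterable[str] = ()) -> int | None:
        """Count of distinct (chrom, position) sites across retained samples.

        Only defined when the table was built from variant records (the
        per-category cells alone cannot recover multi-annotated sites).
        """
        if not self.positions:
            return None
        seen: set[tuple[str, int]] = set()
        for sample, pos in self.positions.items():
            if sample not in set(exclude):
                seen |= pos
        return len(seen)

    @classmethod
    def from_counts(cls, rows: Mapping[str, Mapping[str, int]]) -> "CategoryCountTable":
        """Build from pre-tabulated cells, e.g. a published per-patient table.

        ``rows`` maps sample -> {"SNV:Missense": n, ...}; unknown categories
        are rejected.
        """
        columns = [f"SNV:{c}" for c in ANNOTATION_CATEGORIES] + [
            f"indel:{c}" for c in ANNOTATION_CATEGORIES
        ]
        data = {}
        for sample, cells in rows.items():
            for key in cells:
                cat = key.split(":", 1)[1]
                if cat not in ANNOTATION_CATEGORIES:
                    raise ValidationError(f"unknown annotation category {cat!r}")
            data[sample] = [int(cells.get(col, 0)) for col in columns]
        df = pd.DataFrame.from_dict(data, orient="index", columns=columns)
        return cls(counts=df)


def tabulate_by_annotation(
    variants: Sequence[VariantCall],
    samples: Sequence[str] | None = None,
    exclude: Iterable[str] = (),
) -> CategoryCountTable:
    """Tabulate variants into a per-sample annotation-category count table.

    ``samples`` fixes the row set (zero rows included); by default rows are
    the samples observed.  ``exclude`` only affects the cross-sample totals,
    which the table methods take as an argument — it is recorded here for
    convenience via :meth:`CategoryCountTable.grand_total`.
    """
    del exclude  # exclusion is applied at total-computation time
    if samples is None:
        samples = sorted({v.sample_id for v in variants})
    columns = [f"SNV:{c}" for c in ANNOTATION_CATEGORIES] + [
        f"indel:{c}" for c in ANNOTATION_CATEGORIES
    ]
    df = pd.DataFrame(0, index=list(samples), columns=columns)
    positions: dict[str, set[tuple[str, int]]] = {s: set() for s in samples}
    for v in variants:
        if v.category not in ANNOTATION_CATEGORIES:
            raise ValidationError(f"unknown annotation category {v.category!r}")
        if v.sample_id not in df.index:
            raise ValidationError(f"variant sample {v.sample_id!r} not in sample list")
        df.loc[v.sample_id, f"{v.variant_class}:{v.category}"] += 1
        positions[v.sample_id].add((v.chrom, v.position))
    return CategoryCountTable(counts=df, positions=positions)


# ---------------------------------------------------------------------------
# context-normalized substitution rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Opportunities:
    """Mutational-context counts for one region stratum.

    ``n_c`` counts C:G base pairs (contexts for C>* types), ``n_t`` counts
    T:A pairs, and ``n_cpg_c`` the subset of C's inside CpG dinucleotides
    (so non-CpG C>T opportunity is ``n_c - n_cpg_c``).
    """

    n_c: int
    n_t: int
    n_cpg_c: int

    def __post_init__(self) -> None:
        if min(self.n_c, self.n_t, self.n_cpg_c) < 0 or self.n_cpg_c > self.n_c:
            raise ValidationError("inconsistent opportunity counts")

    def for_type(self, sub_type: str, cpg: bool | None = None) -> int:
        if sub_type.startswith("T>"):
            return self.n_t
        if sub_type == "C>T" and cpg is True:
            return self.n_cpg_c
        if sub_type == "C>T" and cpg is False:
            return self.n_c - self.n_cpg_c
        return self.n_c


@dataclass
class SpectrumTable:
    """Long-form per-sample substitution counts with context/region strata.

    ``counts`` columns: sample, type, region ("exonic"/"non_exonic"),
    cpg (bool; only meaningful for C>T), count.  ``opportunities`` maps
    region stratum to :class:`Opportunities`.
    """

    counts: pd.DataFrame
    opportunities: dict[str, Opportunities]


def _exonic_lookup(exonic_intervals: Iterable[tuple[str, int, int]]):
    merged = merge_intervals(exonic_intervals)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in merged:
        by_chrom.setdefault(chrom, []).append((s, e))

    def is_exonic(chrom: str, position: int) -> bool:
        x = position - 1  # to 0-based
        for s, e in by_chrom.get(chrom, ()):
            if s <= x < e:
                return True
        return False

    return is_exonic, merged


def build_spectrum(
    variants: Sequence[VariantCall],
    exonic_intervals: Iterable[tuple[str, int, int]],
    opportunities: Mapping[str, Opportunities],
) -> SpectrumTable:
    """Classify SNVs and cross-tabulate by sample, type, region and CpG status."""
    if set(opportunities) != {"exonic", "non_exonic"}:
        raise ValidationError("opportunities must cover 'exonic' and 'non_exonic'")
    is_exonic, _ = _exonic_lookup(exonic_intervals)
    rows = []
    for v in variants:
        if v.variant_class != "SNV":
            continue
        label, _, cpg = classify_substitution(v.ref, v.alt, v.context)
        region = "exonic" if is_exonic(v.chrom, v.position) else "non_exonic"
        rows.append((v.sample_id, label, region, cpg))
    df = (
        pd.DataFrame(rows, columns=["sample", "type", "region", "cpg"])
        .value_counts()
        .rename("count")
        .reset_index()
        if rows
        else pd.DataFrame(columns=["sample", "type", "region", "cpg", "count"])
    )
    return SpectrumTable(counts=df, opportunities=dict(opportunities))


def context_normalized_rates(spectrum: SpectrumTable) -> pd.DataFrame:
    """Per-sample, per-type, per-stratum rates = count / context opportunity.

    C>T is reported split by CpG status; other types pool CpG strata.
    Raises on a nonzero count with zero opportunity.
    """
    rows = []
    df = spectrum.counts
    if df.empty:
        return pd.DataFrame(columns=["sample", "type", "region", "cpg", "count", "opportunity", "rate"])
    for (sample, sub_type, region), grp in df.groupby(["sample", "type", "region"]):
        opp = spectrum.opportunities[region]
        if sub_type == "C>T":
            strata = [(True, int(grp.loc[grp.cpg, "count"].sum())),
                      (False, int(grp.loc[~grp.cpg, "count"].sum()))]
        else:
            strata = [(None, int(grp["count"].sum()))]
        for cpg, count in strata:
            opportunity = opp.for_type(sub_type, cpg)
            if opportunity == 0:
                if count > 0:
                    raise ValidationError(
                        f"{sample} {sub_type} ({region}, cpg={cpg}): "
                        f"count {count} with zero opportunity"
                    )
                rate = float("nan")
            else:
                rate = count / opportunity
            rows.append(
                {"sample": sample, "type": sub_type, "region": region,
                 "cpg": cpg, "count": count, "opportunity": opportunity, "rate": rate}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ts/Tv, regional rates, NS/S
# ---------------------------------------------------------------------------


def tstv_by_chromosome(
    variants: Sequence[VariantCall], layout: GenomeLayout
) -> pd.DataFrame:
    """Transition/transversion counts, ratio and percentages per chromosome.

    The ratio is reported as NaN (missing) where the transversion count is
    zero.  Chromosomes with no variants appear with zero counts.
    """
    ts = dict.fromkeys(layout.names, 0)
    tv = dict.fromkeys(layout.names, 0)
    for v in variants:
        if v.variant_class != "SNV":
            continue
        _, transition, _ = classify_substitution(v.ref, v.alt, v.context)
        if transition:
            ts[v.chrom] += 1
        else:
            tv[v.chrom] += 1
    rows = []
    for chrom in layout.names:
        total = ts[chrom] + tv[chrom]
        rows.append(
            {
                "chrom": chrom,
                "ts": ts[chrom],
                "tv": tv[chrom],
                "tstv": (ts[chrom] / tv[chrom]) if tv[chrom] > 0 else float("nan"),
                "pct_ts": (100.0 * ts[chrom] / total) if total else float("nan"),
                "pct_tv": (100.0 * tv[chrom] / total) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegionalRateComparison:
    per_sample: pd.DataFrame  # sample, exonic_rate, non_exonic_rate
    t_statistic: float | None
    p_value: float | None
    note: str = ""


def regional_rate_comparison(
    variants: Sequence[VariantCall],
    exonic_intervals: Iterable[tuple[str, int, int]],
    layout: GenomeLayout,
) -> RegionalRateComparison:
    """Exonic vs non-exonic per-sample mutation rates and the paired t-test.

    Rates are counts per base of stratum footprint; the two-sided paired t
    is on per-sample (non-exonic − exonic) differences and requires at
    least two samples.
    """
    is_exonic, merged = _exonic_lookup(exonic_intervals)
    exonic_bases = sum(e - s for _, s, e in merged)
    non_exonic_bases = layout.total_length - exonic_bases
    if exonic_bases <= 0 or non_exonic_bases <= 0:
        raise ValidationError("both strata must have positive footprint")
    counts: dict[str, list[int]] = {}
    for v in variants:
        ex, nx = counts.setdefault(v.sample_id, [0, 0])
        if is_exonic(v.chrom, v.position):
            counts[v.sample_id][0] = ex + 1
        else:
            counts[v.sample_id][1] = nx + 1
    rows = [
        {"sample": s, "exonic_rate": ex / exonic_bases, "non_exonic_rate": nx / non_exonic_bases}
        for s, (ex, nx) in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["sample", "exonic_rate", "non_exonic_rate"])
    if len(df) < 2:
        return RegionalRateComparison(df, None, None, note="fewer than 2 samples; test skipped")
    t, p = paired_t(df["non_exonic_rate"].to_numpy(), df["exonic_rate"].to_numpy())
    return RegionalRateComparison(df, t, p)


def ns_s_ratio(variants: Sequence[VariantCall]) -> tuple[pd.DataFrame, float]:
    """Per-sample non-synonymous/synonymous ratio and its cross-sample mean.

    Non-synonymous = {Missense, Nonsense, Splice site}; synonymous =
    {Silent}.  A sample with zero synonymous mutations gets a NaN ratio and
    is excluded from the mean.
    """
    ns: dict[str, int] = {}
    s: dict[str, int] = {}
    for v in variants:
        ns.setdefault(v.sample_id, 0)
        s.setdefault(v.sample_id, 0)
        if v.category in NONSYNONYMOUS:
            ns[v.sample_id] += 1
        elif v.category in SYNONYMOUS:
            s[v.sample_id] += 1
    rows = []
    for sample in sorted(ns):
        ratio = ns[sample] / s[sample] if s[sample] > 0 else float("nan")
        rows.append({"sample": sample, "nonsynonymous": ns[sample],
                     "synonymous": s[sample], "ratio": ratio})
    df = pd.DataFrame(rows, columns=["sample", "nonsynonymous", "synonymous", "ratio"])
    defined = df["ratio"].dropna()
    mean = float(defined.mean()) if len(defined) else float("nan")
    return df, mean
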