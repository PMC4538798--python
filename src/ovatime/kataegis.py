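"""Rainfall (inter-mutation distance) analysis and kataegis cluster calling.

Distances are computed per chromosome within one sample's genome ordering;
chromosome boundaries never produce a distance.  Candidate kataegis calls
are maximal runs of consecutive mutations whose mean inter-mutation
distance stays below a threshold — the field-standard >= 6 mutations with
mean spacing <= 1 kb by default.  A mappability pre-filter drops variants
whose flanking window maps to more than three genomic locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import GenomeLayout, ValidationError, VariantCall
from .spectrum import classify_substitution
from .stats import binomial_two_sided

__all__ = [
    "RainfallPoint",
    "KataegisCall",
    "mappability_filter",
    "rainfall",
    "detect_clusters",
    "chromosome_type_enrichment",
]

DEFAULT_MIN_CLUSTER_SIZE = 6
DEFAULT_MAX_MEAN_DISTANCE = 1_000  # bases
DEFAULT_MAX_MAP_LOCATIONS = 3


@dataclass(frozen=True)
class RainfallPoint:
    """One mutation on the rainfall plot.

    ``distance`` is the gap to the previous mutation on the same
    chromosome, ``None`` for the first mutation of each chromosome.
    """

    chrom: str
    position: int
    distance: int | None
    sub_type: str


@dataclass(frozen=True)
class KataegisCall:
    chrom: str
    start: int
    end: int
    count: int
    mean_distance: float
    dominant_type: str


def mappability_filter(
    variants: Sequence[VariantCall],
    max_locations: int = DEFAULT_MAX_MAP_LOCATIONS,
    homolog_is_map_count: bool = True,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop variants whose flanking window maps to too many genomic locations.

    The per-variant mapping-location count is a precomputed annotation
    (carried on ``homolog_count``); a variant is kept when its count is
    <= ``max_locations``.  Returns ``(kept, removed)``.
    """
    del homolog_is_map_count  # single annotation channel in this data model
    kept: list[VariantCall] = []
    removed: list[VariantCall] = []
    for v in variants:
        if v.homolog_count is None:
            raise ValidationError(
                f"{v.chrom}:{v.position}: mapping-location annotation missing"
            )
        (kept if v.homolog_count <= max_locations else removed).append(v)
    return kept, removed


def rainfall(
    variants: Sequence[VariantCall], layout: GenomeLayout
) -> list[RainfallPoint]:
    """Per-chromosome inter-mutation distances for one sample's SNVs.

    Input order is irrelevant: variants are sorted by (chromosome rank,
    position).  Duplicate positions yield distance 0.
    """
    snvs = sorted(
        (v for v in variants if v.variant_class == "SNV"),
        key=lambda v: (layout.rank(v.chrom), v.position),
    )
    points: list[RainfallPoint] = []
    prev: VariantCall | None = None
    for v in snvs:
        label, _, _ = classify_substitution(v.ref, v.alt, v.context)
        if prev is not None and prev.chrom == v.chrom:
            dist: int | None = v.position - prev.position
        else:
            dist = None
        points.append(RainfallPoint(v.chrom, v.position, dist, label))
        prev = v
    return points


def detect_clusters(
    points: Sequence[RainfallPoint],
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    max_mean_distance: float = DEFAULT_MAX_MEAN_DISTANCE,
) -> list[KataegisCall]:
    """Call maximal runs of closely spaced mutations.

    Scanning left to right within each chromosome, a run starting at
    mutation *i* is extended while the mean inter-mutation distance of the
    run stays <= ``max_mean_distance``; runs with >= ``min_size`` members
    become calls.  Calls never overlap and the procedure is deterministic
    and idempotent.
    """
    if min_size < 2 or max_mean_distance <= 0:
        raise ValidationError("need min_size >= 2 and positive distance threshold")
    by_chrom: dict[str, list[RainfallPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chrom, []).append(p)
    calls: list[KataegisCall] = []
    for chrom, pts in by_chrom.items():
        pts = sorted(pts, key=lambda p: p.position)
        i = 0
        n = len(pts)
        while i < n:
            j = i
            gap_sum = 0
            # extend while the running mean gap stays under threshold
            while j + 1 < n:
                gap = pts[j + 1].position - pts[j].position
                if (gap_sum + gap) / (j + 1 - i) > max_mean_distance:
                    break
                gap_sum += gap
                j += 1
            size = j - i + 1
            if size >= min_size:
                types = pd.Series([p.sub_type for p in pts[i : j + 1]])
                calls.append(
                    KataegisCall(
                        chrom=chrom,
                        start=pts[i].position,
                        end=pts[j].position,
                        count=size,
                        mean_distance=gap_sum / (size - 1),
                        dominant_type=types.mode().iloc[0],
                    )
                )
                i = j + 1
            else:
                i += 1
    return calls


def chromosome_type_enrichment(
    variants: Sequence[VariantCall],
    layout: GenomeLayout,
    sub_type: str = "T>C",
) -> pd.DataFrame:
    """Per-chromosome enrichment of one substitution type vs the genome-wide rate.

    Binomial test of the chromosome's count of ``sub_type`` against the
    genome-wide fraction — the chromosome-scale analogue of a kataegis
    call, aimed at whole-chromosome hypermutation (e.g. a chromosome with
    excess T>C substitutions).
    """
    labels = [
        (v.chrom, classify_substitution(v.ref, v.alt, v.context)[0])
        for v in variants
        if v.variant_class == "SNV"
    ]
    total = len(labels)
    if total == 0:
        return pd.DataFrame(columns=["chrom", "n", "type_count", "fraction", "genome_fraction", "p_value"])
    genome_frac = sum(1 for _, t in labels if t == sub_type) / total
    rows = []
    for chrom in layout.names:
        chrom_labels = [t for c, t in labels if c == chrom]
        n = len(chrom_labels)
        k = sum(1 for t in chrom_labels if t == sub_type)
        rows.append(
            {
                "chrom": chrom,
                "n": n,
                "type_count": k,
                "fraction": k / n if n else float("nan"),
                "genome_fraction": genome_frac,
                "p_value": binomial_two_sided(k, n, genome_frac) if n and 0 < genome_frac < 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def rainfall_table(points: Sequence[RainfallPoint]) -> pd.DataFrame:
    """Plot-ready rainfall TSV rows: position, distance, log10 distance, type."""
    import math

    rows = []
    for p in points:
        rows.append(
            {
                "chrom": p.chrom,
                "position": p.position,
                "distance": "" if p.distance is None else p.distance,
                "log10_distance": (
                    "" if p.distance is None or p.distance <= 0 else math.log10(p.distance)
                ),
                "type": p.sub_type,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "position", "distance", "log10_distance", "type"])
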