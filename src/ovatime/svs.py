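"""Structural-variant deduplication and proximity clustering.

Two SVs are duplicates when both corresponding breakpoints lie on matching
chromosomes within a small tolerance (10 bp by default); duplicate groups
are closed transitively and resolved to the first event in sorted order.
Clustering links unique SVs whose breakpoints come within 1 Mb of each
other on the same chromosome and reports connected components; singleton
components are unclustered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import SVEvent, ValidationError

__all__ = [
    "SvClusterReport",
    "dedup_svs",
    "cluster_svs",
    "clustered_fraction",
]

DEDUP_TOLERANCE = 10  # bp
CLUSTER_WINDOW = 1_000_000  # bp


@dataclass
class SvClusterReport:
    unique_svs: list[SVEvent]
    clusters: list[list[SVEvent]]  # only components with >= 2 members
    clustered_count: int
    clustered_fraction: float


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _sort_key(sv: SVEvent):
    return (sv.chrom_a, sv.pos_a, sv.chrom_b, sv.pos_b, sv.sv_type)


def _is_duplicate(a: SVEvent, b: SVEvent, tolerance: int) -> bool:
    return (
        a.chrom_a == b.chrom_a
        and a.chrom_b == b.chrom_b
        and abs(a.pos_a - b.pos_a) <= tolerance
        and abs(a.pos_b - b.pos_b) <= tolerance
    )


def dedup_svs(svs: Sequence[SVEvent], tolerance: int = DEDUP_TOLERANCE) -> list[SVEvent]:
    """Collapse near-identical SVs (both ends within ``tolerance``).

    Duplicate groups are transitive closures of the pairwise relation;
    each group is represented by its first member in canonical sorted
    order, so the result is permutation-invariant.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    events = sorted((sv.canonical() for sv in svs), key=_sort_key)
    n = len(events)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _is_duplicate(events[i], events[j], tolerance):
                uf.union(i, j)
    representatives: dict[int, SVEvent] = {}
    for i, sv in enumerate(events):
        root = uf.find(i)
        if root not in representatives:
            representatives[root] = sv
    return sorted(representatives.values(), key=_sort_key)


def _breakpoints(sv: SVEvent) -> tuple[tuple[str, int], tuple[str, int]]:
    return (sv.chrom_a, sv.pos_a), (sv.chrom_b, sv.pos_b)


def _linked(a: SVEvent, b: SVEvent, window: int) -> bool:
    for chrom_a, pos_a in _breakpoints(a):
        for chrom_b, pos_b in _breakpoints(b):
            if chrom_a == chrom_b and abs(pos_a - pos_b) <= window:
                return True
    return False


def cluster_svs(svs: Sequence[SVEvent], window: int = CLUSTER_WINDOW) -> SvClusterReport:
    """Group unique SVs into proximity clusters (connected components).

    Interchromosomal events participate through each breakpoint
    independently.  ``clustered_fraction`` is the share of unique SVs in
    components of size >= 2; it is 0.0 for an empty input.
    """
    if window <= 0:
        raise ValidationError("window must be positive")
    events = sorted((sv.canonical() for sv in svs), key=_sort_key)
    n = len(events)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _linked(events[i], events[j], window):
                uf.union(i, j)
    components: dict[int, list[SVEvent]] = {}
    for i, sv in enumerate(events):
        components.setdefault(uf.find(i), []).append(sv)
    clusters = [grp for grp in components.values() if len(grp) >= 2]
    clustered = sum(len(grp) for grp in clusters)
    return SvClusterReport(
        unique_svs=events,
        clusters=clusters,
        clustered_count=clustered,
        clustered_fraction=clustered / n if n else 0.0,
    )


def clustered_fraction(
    svs: Sequence[SVEvent],
    tolerance: int = DEDUP_TOLERANCE,
    window: int = CLUSTER_WINDOW,
) -> float:
    """Dedup then cluster; the share of unique SVs that are clustered."""
    return cluster_svs(dedup_svs(svs, tolerance), window).clustered_fraction
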