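"""Synthetic tumor/normal genome generator with ground truth.

Emulates the statistical structure the downstream stages assume: a diploid
genome carrying hemizygous deletions in a clone of known fraction, somatic
SNVs timed before or after those deletions, binomial read sampling around
the expected mutant allele frequency, a CpG-enriched C>T substitution
spectrum (exonic enrichment only), optional kataegis clusters and
clustered/unclustered SV breakpoints, plus heterozygous germline sites
whose tumor B-allele frequencies reflect LOH.  Every generated quantity is
recorded in a :class:`TumorTruth` so parameter-recovery tests have an
oracle.

All randomness flows through one ``numpy`` Generator derived from the
config seed; the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_LAYOUT,
    GeneModel,
    GenomeLayout,
    SampleProfile,
    Segment,
    SVEvent,
    ValidationError,
    VariantCall,
)
from .timing import TimingPair, expected_maf

__all__ = [
    "SimConfig",
    "KataegisSpec",
    "TumorTruth",
    "generate_dataset",
    "generate_cohort",
    "spike_kataegis",
    "spike_sv_clusters",
    "default_exons",
    "default_gene_models",
    "synthetic_opportunities",
    "simulate_timing_pairs",
]

_SUBSTITUTIONS_12 = (
    "C>A", "C>G", "C>T", "T>A", "T>C", "T>G",
    "G>T", "G>C", "G>A", "A>T", "A>G", "A>C",
)

#: Default 12-type weights reproducing the study's printed spectrum shape:
#: C>T transitions are the most common type (27%), T>G transversions the
#: rarest (8%), and transitions outnumber transversions overall (55%), as
#: in every chromosome of the sequenced cohort.
_FOLDED_WEIGHTS = {"C>T": 0.27, "T>C": 0.28, "T>G": 0.08,
                   "C>A": 0.13, "C>G": 0.12, "T>A": 0.12}
_FOLD = {"G>A": "C>T", "A>G": "T>C", "A>C": "T>G",
         "G>T": "C>A", "G>C": "C>G", "A>T": "T>A"}
_DEFAULT_WEIGHTS = {
    t: _FOLDED_WEIGHTS.get(t, _FOLDED_WEIGHTS.get(_FOLD.get(t, ""), 0.0)) / 2
    for t in _SUBSTITUTIONS_12
}

_NONCODING_CATEGORIES = ("Intergenic", "Intron", "3'Flank", "5'Flank", "3'UTR", "5'UTR")
_NONCODING_WEIGHTS = (0.55, 0.30, 0.05, 0.04, 0.03, 0.03)
_CODING_SNV_CATEGORIES = ("Missense", "Silent", "Nonsense", "Splice site")
_CODING_SNV_WEIGHTS = (0.62, 0.28, 0.06, 0.04)


@dataclass(frozen=True)
class KataegisSpec:
    """Specification of spiked kataegis clusters."""

    count: int = 1
    size: int = 10
    spacing: int = 200  # mean intra-cluster gap in bases
    sub_type: str = "T>C"
    chrom: str | None = None

    def __post_init__(self) -> None:
        if self.count < 0 or (self.count > 0 and self.size < 2) or self.spacing <= 0:
            raise ValidationError("kataegis spec needs count >= 0, size >= 2, spacing > 0")


@dataclass
class SimConfig:
    """Study conditions for one synthetic tumor/normal pair.

    Defaults mirror the sequencing study this pipeline re-implements:
    mean read depth 46 in tumor and normal, a C>T-dominated spectrum
    (27% C>T, 8% T>G), CpG C>T enrichment (x3) confined to exonic
    regions, purity 0.6 with a single clonal population, and a desk-scale
    three-chromosome 50 Mb mini-genome.
    """

    seed: int = 0
    layout: GenomeLayout = DEFAULT_LAYOUT
    sample_id: str = "S1"
    purity: float = 0.6
    clone_fractions: tuple[float, ...] = (1.0,)
    ploidy: float = 2.0
    n_deletions: int = 5
    deletion_mean_length: int = 8_000_000
    deletion_min_length: int = 1_000_000
    n_snvs: int = 500
    spectrum_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    cpg_fraction_exonic: float = 0.08
    cpg_fraction_non_exonic: float = 0.02
    cpg_ct_multiplier: float = 3.0
    non_exonic_rate_multiplier: float = 2.0
    mean_depth_tumor: int = 46
    mean_depth_normal: int = 46
    poisson_depth: bool = False
    frac_before_deletion: float = 1.0
    f_after: float = 0.5
    kataegis: KataegisSpec = KataegisSpec(count=0)
    n_svs: int = 0
    sv_clustered_fraction: float = 0.0
    n_germline_het: int = 200
    log2_noise_sd: float = 0.05
    exons: tuple[tuple[str, int, int], ...] | None = None

    def validate(self) -> "SimConfig":
        if sum(self.clone_fractions) > 1.0 + 1e-12:
            raise ValidationError("clone fractions must sum to at most 1")
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError("purity must lie in [0, 1]")
        if min(self.mean_depth_tumor, self.mean_depth_normal) < 1:
            raise ValidationError("mean depth must be >= 1")
        if min(self.n_deletions, self.n_snvs, self.n_svs, self.n_germline_het) < 0:
            raise ValidationError("counts must be non-negative")
        if not 0.0 <= self.sv_clustered_fraction <= 1.0:
            raise ValidationError("SV clustered fraction must lie in [0, 1]")
        if not 0.0 <= self.frac_before_deletion <= 1.0:
            raise ValidationError("frac_before_deletion must lie in [0, 1]")
        return self


@dataclass
class TumorTruth:
    """Ground truth for one generated dataset."""

    purity: float
    clone_fractions: tuple[float, ...]
    variant_truth: pd.DataFrame  # timing, f, m_true, on_deletion, kataegis_cluster
    segment_truth: pd.DataFrame  # chrom, start, end, deleted_fraction, loh
    kataegis_clusters: list[dict]
    sv_clustered: list[bool]
    germline_het: pd.DataFrame  # chrom, position, loh, expected_baf, tumor_alt, tumor_depth


# ---------------------------------------------------------------------------
# default annotation geometry
# ---------------------------------------------------------------------------


def default_exons(layout: GenomeLayout) -> tuple[tuple[str, int, int], ...]:
    """Ten 150 kb exon blocks per chromosome, evenly spaced (~3% exonic)."""
    exons = []
    for chrom, length in zip(layout.names, layout.lengths):
        step = length // 10
        for k in range(10):
            start = k * step + step // 2
            exons.append((chrom, start, min(start + 150_000, length)))
    return tuple(exons)


def default_gene_models(layout: GenomeLayout, per_chrom: int = 3) -> list[GeneModel]:
    """A few 100 kb genes per chromosome at fixed positions."""
    genes = []
    for chrom, length in zip(layout.names, layout.lengths):
        step = length // (per_chrom + 1)
        for k in range(per_chrom):
            start = (k + 1) * step
            genes.append(
                GeneModel(
                    name=f"GENE_{chrom}_{k + 1}",
                    intervals=((chrom, start, start + 100_000),),
                )
            )
    return genes


def synthetic_opportunities(
    layout: GenomeLayout,
    exons: Sequence[tuple[str, int, int]],
    gc_fraction: float = 0.42,
    cpg_fraction_exonic: float = 0.08,
    cpg_fraction_non_exonic: float = 0.02,
) -> dict:
    """Mutational-context counts for the synthetic genome.

    The mini-genome carries no literal sequence; context opportunities are
    derived from an assumed base composition: ``gc_fraction`` of positions
    are C:G pairs, and the stated fraction of C's sit in CpG dinucleotides
    per stratum (CpG-richer in exons).
    """
    from .spectrum import Opportunities

    exon_bases = sum(e - s for _, s, e in exons)
    non_exon_bases = layout.total_length - exon_bases
    out = {}
    for name, bases, cpg_frac in (
        ("exonic", exon_bases, cpg_fraction_exonic),
        ("non_exonic", non_exon_bases, cpg_fraction_non_exonic),
    ):
        n_c = int(round(gc_fraction * bases))
        out[name] = Opportunities(
            n_c=n_c, n_t=bases - n_c, n_cpg_c=int(round(cpg_frac * n_c))
        )
    return out


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------


def _place_deletions(config: SimConfig, rng: np.random.Generator):
    """Non-overlapping hemizygous deletion segments with clone assignment."""
    layout = config.layout
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
    deletions = []
    attempts = 0
    while len(deletions) < config.n_deletions:
        attempts += 1
        if attempts > 200 * max(1, config.n_deletions):
            raise ValidationError("cannot place deletion segments without overlap")
        chrom = layout.names[int(rng.integers(len(layout.names)))]
        length = int(
            max(config.deletion_min_length, rng.exponential(config.deletion_mean_length))
        )
        chrom_len = layout.length_of(chrom)
        if length >= chrom_len:
            continue
        start = int(rng.integers(0, chrom_len - length))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        clone = float(config.clone_fractions[int(rng.integers(len(config.clone_fractions)))])
        deletions.append({"chrom": chrom, "start": start, "end": end, "clone": clone})
    return deletions, placed


def _segments_from_deletions(config: SimConfig, deletions, rng: np.random.Generator):
    """Deletion segments plus neutral complement tiling each chromosome."""
    x = config.purity
    segments: list[Segment] = []
    for chrom, length in zip(config.layout.names, config.layout.lengths):
        dels = sorted((d for d in deletions if d["chrom"] == chrom), key=lambda d: d["start"])
        cursor = 0
        for d in dels:
            if d["start"] > cursor:
                segments.append(
                    Segment(
                        chrom=chrom, start=cursor, end=d["start"],
                        log2=float(rng.normal(0.0, config.log2_noise_sd)),
                        copy_number=2, loh=False, sample_id=config.sample_id,
                    )
                )
            cna = d["clone"] * x
            true_log2 = math.log2(1.0 - cna / 2.0)
            segments.append(
                Segment(
                    chrom=chrom, start=d["start"], end=d["end"],
                    log2=float(true_log2 + rng.normal(0.0, config.log2_noise_sd)),
                    copy_number=1, loh=True, sample_id=config.sample_id,
                )
            )
            cursor = d["end"]
        if cursor < length:
            segments.append(
                Segment(
                    chrom=chrom, start=cursor, end=length,
                    log2=float(rng.normal(0.0, config.log2_noise_sd)),
                    copy_number=2, loh=False, sample_id=config.sample_id,
                )
            )
    return segments


def _depth(config: SimConfig, mean: int, rng: np.random.Generator) -> int:
    if config.poisson_depth:
        return max(1, int(rng.poisson(mean)))
    return mean


def _context_for(sub_type: str, cpg: bool, rng: np.random.Generator) -> str:
    """A 3-mer consistent with the (unfolded) substitution type and CpG flag."""
    ref = sub_type[0]
    bases = "ACGT"
    left = bases[int(rng.integers(4))]
    if ref == "C":
        right = "G" if cpg else "ACT"[int(rng.integers(3))]
    elif ref == "G":  # pyrimidine-strand C precedes on the reverse strand
        left = "C" if cpg else "AGT"[int(rng.integers(3))]
        right = bases[int(rng.integers(4))]
    else:
        right = bases[int(rng.integers(4))]
    return f"{left}{ref}{right}"


def _sample_position(config: SimConfig, exons, rng: np.random.Generator):
    """Position sampling with the non-exonic/exonic rate contrast."""
    layout = config.layout
    exon_bases = sum(e - s for _, s, e in exons)
    non_exon_bases = layout.total_length - exon_bases
    w_ex = exon_bases
    w_nx = config.non_exonic_rate_multiplier * non_exon_bases
    exonic = rng.random() < w_ex / (w_ex + w_nx)
    if exonic:
        lengths = np.array([e - s for _, s, e in exons], dtype=float)
        idx = int(rng.choice(len(exons), p=lengths / lengths.sum()))
        chrom, s, e = exons[idx]
        pos = int(rng.integers(s, e)) + 1
    else:
        # uniform over the genome, rejecting exonic hits
        for _ in range(1000):
            lengths = np.array(layout.lengths, dtype=float)
            ci = int(rng.choice(len(layout.names), p=lengths / lengths.sum()))
            chrom = layout.names[ci]
            pos = int(rng.integers(0, layout.lengths[ci])) + 1
            if not any(c == chrom and s < pos <= e for c, s, e in exons):
                break
    return chrom, pos, exonic


def _make_snv(
    config: SimConfig,
    chrom: str,
    pos: int,
    exonic: bool,
    m_true: float,
    rng: np.random.Generator,
    sub_type: str | None = None,
    cpg: bool | None = None,
) -> VariantCall:
    if sub_type is None:
        types = list(config.spectrum_weights)
        weights = np.array([config.spectrum_weights[t] for t in types], dtype=float)
        sub_type = str(types[int(rng.choice(len(types), p=weights / weights.sum()))])
    if cpg is None:
        folded_ct = sub_type in ("C>T", "G>A")
        base = config.cpg_fraction_exonic if exonic else config.cpg_fraction_non_exonic
        p_cpg = min(0.95, base * config.cpg_ct_multiplier) if exonic else base
        cpg = bool(folded_ct and rng.random() < p_cpg)
    ref, alt = sub_type.split(">")
    t_depth = _depth(config, config.mean_depth_tumor, rng)
    t_alt = int(rng.binomial(t_depth, m_true))
    fwd = int(rng.binomial(t_alt, 0.5)) if t_alt else 0
    g_depth = _depth(config, config.mean_depth_normal, rng)
    if exonic:
        cats, wts = _CODING_SNV_CATEGORIES, _CODING_SNV_WEIGHTS
    else:
        cats, wts = _NONCODING_CATEGORIES, _NONCODING_WEIGHTS
    category = str(cats[int(rng.choice(len(cats), p=np.array(wts) / sum(wts)))])
    return VariantCall(
        chrom=chrom, position=pos, ref=ref, alt=alt,
        tumor_depth=t_depth, tumor_alt=t_alt,
        germline_depth=g_depth, germline_alt=0,
        somatic_score=float(np.round(rng.normal(60.0, 10.0), 1)),
        bq_mutant=tuple(int(q) for q in rng.integers(25, 41, size=t_alt)),
        alt_forward=fwd, alt_reverse=t_alt - fwd,
        strand_bias=float(np.round(rng.uniform(0.0, 20.0), 1)),
        dbsnp_maf=None, homolog_count=int(rng.integers(0, 3)),
        category=category, variant_class="SNV",
        context=_context_for(sub_type, cpg, rng),
        sample_id=config.sample_id,
    ).validate()


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def generate_dataset(config: SimConfig):
    """Generate one tumor/normal dataset plus its ground truth.

    Returns ``(variants, segments, svs, profile, truth)``.  Deterministic
    given ``config.seed``; tumor mutant read counts are binomial draws at
    the model-expected MAF per site, germline mutant reads are zero at
    somatic sites, and heterozygous germline sites are emitted separately
    (in the truth record) for LOH structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    exons = config.exons if config.exons is not None else default_exons(layout)
    x = config.purity

    deletions, _ = _place_deletions(config, rng)
    segments = _segments_from_deletions(config, deletions, rng)

    variants: list[VariantCall] = []
    truth_rows = []
    for _ in range(config.n_snvs):
        chrom, pos, exonic = _sample_position(config, exons, rng)
        hit = next(
            (d for d in deletions if d["chrom"] == chrom and d["start"] < pos <= d["end"]),
            None,
        )
        if hit is not None:
            before = bool(rng.random() < config.frac_before_deletion)
            f = 1.0 if before else config.f_after
            m_true = expected_maf(x, hit["clone"], f)
            timing = "before" if before else "after"
        else:
            f = float("nan")
            m_true = x / 2.0  # clonal heterozygous SNV on a diploid background
            timing = "none"
        variants.append(_make_snv(config, chrom, pos, exonic, m_true, rng))
        truth_rows.append(
            {"chrom": chrom, "position": pos, "timing": timing, "f": f,
             "m_true": m_true, "on_deletion": hit is not None, "kataegis_cluster": -1}
        )

    clusters: list[dict] = []
    if config.kataegis.count > 0:
        variants, clusters, kat_truth = spike_kataegis(
            variants, layout, config.kataegis, rng=rng, config=config
        )
        truth_rows.extend(kat_truth)

    svs: list[SVEvent] = []
    sv_labels: list[bool] = []
    if config.n_svs > 0:
        svs, sv_labels = spike_sv_clusters(
            layout, config.n_svs, config.sv_clustered_fraction, rng=rng,
            sample_id=config.sample_id,
        )

    germline_het = _germline_het_sites(config, deletions, rng)

    profile = SampleProfile(config.sample_id, purity=x, ploidy=config.ploidy)
    truth = TumorTruth(
        purity=x,
        clone_fractions=tuple(config.clone_fractions),
        variant_truth=pd.DataFrame(truth_rows),
        segment_truth=pd.DataFrame(
            [
                {"chrom": d["chrom"], "start": d["start"], "end": d["end"],
                 "deleted_fraction": d["clone"] * x, "loh": True}
                for d in deletions
            ]
        ),
        kataegis_clusters=clusters,
        sv_clustered=sv_labels,
        germline_het=germline_het,
    )
    return variants, segments, svs, profile, truth


def _germline_het_sites(config: SimConfig, deletions, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    layout = config.layout
    lengths = np.array(layout.lengths, dtype=float)
    for _ in range(config.n_germline_het):
        ci = int(rng.choice(len(layout.names), p=lengths / lengths.sum()))
        chrom = layout.names[ci]
        pos = int(rng.integers(0, layout.lengths[ci])) + 1
        hit = next(
            (d for d in deletions if d["chrom"] == chrom and d["start"] < pos <= d["end"]),
            None,
        )
        if hit is not None:
            cna = hit["clone"] * config.purity
            # B allele lost in deleted cells: 1-cna B copies over 2-cna total.
            baf = (1.0 - cna) / (2.0 - cna)
            loh = True
        else:
            baf = 0.5
            loh = False
        depth = _depth(config, config.mean_depth_tumor, rng)
        rows.append(
            {"chrom": chrom, "position": pos, "loh": loh, "expected_baf": baf,
             "tumor_alt": int(rng.binomial(depth, baf)), "tumor_depth": depth}
        )
    return pd.DataFrame(rows)


def spike_kataegis(
    variants: Sequence[VariantCall],
    layout: GenomeLayout,
    spec: KataegisSpec,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
):
    """Insert tightly spaced mutation clusters; background variants untouched.

    Intra-cluster gaps are capped exponentials with the spec's mean
    spacing (cap 10x the mean), so a spacing of 200 bp keeps every
    consecutive intra-cluster distance under 2 kb.  Returns
    ``(variants, clusters, per_variant_truth_rows)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if config is None:
        config = SimConfig(layout=layout)
    out = list(variants)
    clusters = []
    truth_rows = []
    for ci in range(spec.count):
        chrom = spec.chrom or layout.names[int(rng.integers(len(layout.names)))]
        span_budget = spec.size * spec.spacing * 10
        chrom_len = layout.length_of(chrom)
        if span_budget >= chrom_len:
            raise ValidationError(f"kataegis cluster does not fit on {chrom}")
        start = int(rng.integers(1, chrom_len - span_budget))
        pos = start
        positions = [pos]
        for _ in range(spec.size - 1):
            gap = min(int(rng.exponential(spec.spacing)) + 1, 10 * spec.spacing)
            pos += gap
            positions.append(pos)
        m_true = config.purity / 2.0
        for p in positions:
            out.append(
                _make_snv(
                    config, chrom, p, exonic=False, m_true=m_true, rng=rng,
                    sub_type=spec.sub_type, cpg=False,
                )
            )
            truth_rows.append(
                {"chrom": chrom, "position": p, "timing": "none", "f": float("nan"),
                 "m_true": m_true, "on_deletion": False, "kataegis_cluster": ci}
            )
        clusters.append(
            {"chrom": chrom, "start": positions[0], "end": positions[-1],
             "size": spec.size, "sub_type": spec.sub_type}
        )
    return out, clusters, truth_rows


def spike_sv_clusters(
    layout: GenomeLayout,
    n_svs: int,
    clustered_fraction: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    sample_id: str = "",
):
    """Plant SVs so that exactly round(fraction * n) are 1 Mb-clustered.

    Events occupy well-separated 1.2 Mb slots on a 4 Mb grid: members of a
    clustered group share a slot (all breakpoints within 0.6 Mb, hence
    mutually linked under the 1 Mb rule), while distinct slots keep every
    cross-slot breakpoint distance above 2 Mb.  Returns
    ``(svs, clustered_labels)``.
    """
    if not 0.0 <= clustered_fraction <= 1.0:
        raise ValidationError("clustered fraction must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_clustered = int(round(clustered_fraction * n_svs))
    if n_clustered == 1:
        raise ValidationError("cannot plant a clustered group of size 1")
    group_sizes: list[int] = []
    remaining = n_clustered
    while remaining > 0:
        size = 3 if remaining in (3, 5) or (remaining > 4 and rng.random() < 0.5) else 2
        size = min(size, remaining)
        if size < 2:  # remaining == 1 cannot happen given the 3/5 handling
            raise ValidationError("cannot plant a clustered group of size 1")
        group_sizes.append(size)
        remaining -= size
    n_single = n_svs - n_clustered

    slot_step = 4_000_000
    slots = []
    for chrom, length in zip(layout.names, layout.lengths):
        pos = 1_000_000
        while pos + 1_200_000 < length:
            slots.append((chrom, pos))
            pos += slot_step
    needed = len(group_sizes) + n_single
    if needed > len(slots):
        raise ValidationError(
            f"cannot place {n_svs} SVs: need {needed} slots, layout offers {len(slots)}"
        )
    order = rng.permutation(len(slots))[:needed]
    sv_types = ("deletion", "duplication", "inversion")

    svs: list[SVEvent] = []
    labels: list[bool] = []

    def _make_sv(chrom: str, slot_pos: int, width: int) -> SVEvent:
        pos_a = slot_pos + int(rng.integers(0, width))
        span = int(rng.integers(10_000, 100_000))
        return SVEvent(
            chrom_a=chrom, pos_a=pos_a, chrom_b=chrom, pos_b=pos_a + span,
            sv_type=str(sv_types[int(rng.integers(len(sv_types)))]),
            sample_id=sample_id,
        ).canonical()

    slot_iter = iter(order)
    for size in group_sizes:
        chrom, slot_pos = slots[next(slot_iter)]
        for _ in range(size):
            svs.append(_make_sv(chrom, slot_pos, width=400_000))
            labels.append(True)
    for _ in range(n_single):
        chrom, slot_pos = slots[next(slot_iter)]
        svs.append(_make_sv(chrom, slot_pos, width=1_000_000))
        labels.append(False)
    return svs, labels


def generate_cohort(
    n_samples: int = 16,
    seed: int = 0,
    base_config: SimConfig | None = None,
    sample_overrides: Sequence[dict] | None = None,
):
    """Generate a cohort of tumor/normal datasets with per-sample seeds.

    Sample i uses seed ``(seed * 1000 + i) % 2**31`` and id ``S01..Snn``.
    ``sample_overrides`` optionally patches config fields per sample.
    Returns a list of ``(variants, segments, svs, profile, truth)`` tuples.
    """
    base = base_config or SimConfig()
    out = []
    for i in range(n_samples):
        overrides = dict(sample_overrides[i]) if sample_overrides else {}
        cfg = dataclasses.replace(
            base,
            seed=(seed * 1000 + i) % 2**31,
            sample_id=f"S{i + 1:02d}",
            **overrides,
        )
        out.append(generate_dataset(cfg))
    return out


def simulate_timing_pairs(
    n_regions: int,
    depth: int,
    purity: float,
    clone_fraction: float,
    f_true: float,
    rng: np.random.Generator,
    snvs_per_region: int = 1,
) -> list[TimingPair]:
    """Timing observations with binomial read noise and exact cna = c*x.

    The per-region MMAF is the mean of ``snvs_per_region`` binomial draws
    at the model-expected MAF; cna is supplied exactly, as when purity and
    clone fraction are known.
    """
    cna = clone_fraction * purity
    m_true = expected_maf(purity, clone_fraction, f_true)
    pairs = []
    for i in range(n_regions):
        draws = rng.binomial(depth, m_true, size=snvs_per_region) / depth
        pairs.append(
            TimingPair(
                sample_id=f"R{i + 1}", region="region", m=float(draws.mean()),
                cna=cna, n_snvs=snvs_per_region,
                clone_fraction=clone_fraction, purity=purity,
            ).validate()
        )
    return pairs
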