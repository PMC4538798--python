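"""Shared domain types, coordinate conventions and file I/O.

Conventions used throughout the package:

* variant positions are 1-based (VCF convention);
* segment and gene intervals are 0-based half-open (BED convention);
* chromosome order is the natural order of the active :class:`GenomeLayout`.

All other modules build on the types defined here; every reader validates
the type invariants on construction so malformed inputs fail loudly with
the offending record identified.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

__all__ = [
    "ANNOTATION_CATEGORIES",
    "CODING_CATEGORIES",
    "GenomeLayout",
    "VariantCall",
    "Segment",
    "SVEvent",
    "SampleProfile",
    "GeneModel",
    "FormatError",
    "ValidationError",
    "read_variants",
    "write_variants",
    "read_segments",
    "write_segments",
    "read_svs",
    "write_svs",
    "read_gene_models",
    "write_table",
]

#: The fixed functional-annotation vocabulary used for mutation tabulation.
#: Unknown categories are rejected rather than coerced so that per-category
#: counts stay auditable.
ANNOTATION_CATEGORIES = (
    "3'Flank",
    "Missense",
    "5'UTR",
    "Nonsense",
    "Intergenic",
    "Splice site",
    "Silent",
    "5'Flank",
    "De novo start InFrame",
    "3'UTR",
    "Intron",
    "Frame shift del",
    "Frame shift ins",
)

#: Categories counted as coding or splice-site in cohort summaries.
CODING_CATEGORIES = (
    "Missense",
    "Nonsense",
    "Splice site",
    "Silent",
    "De novo start InFrame",
    "Frame shift del",
    "Frame shift ins",
)


class FormatError(ValueError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths for a (possibly synthetic) genome."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValidationError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValidationError("chromosome lengths must be strictly positive")

    @classmethod
    def from_dict(cls, lengths: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths), tuple(lengths.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def rank(self, chrom: str) -> int:
        """Sort key for the natural chromosome order of this layout."""
        try:
            return self.names.index(chrom)
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


@dataclass
class VariantCall:
    """One somatic variant with tumor/germline read support and annotations.

    ``position`` is 1-based.  ``bq_mutant`` holds per-read Phred base
    qualities of the tumor mutant reads.  ``dbsnp_maf`` is ``None`` when the
    site is not in dbSNP, else the catalogued minor allele frequency.
    """

    chrom: str
    position: int
    ref: str
    alt: str
    tumor_depth: int
    tumor_alt: int
    germline_depth: int
    germline_alt: int
    somatic_score: float
    bq_mutant: tuple[int, ...] = ()
    alt_forward: int = 0
    alt_reverse: int = 0
    strand_bias: float = 0.0
    dbsnp_maf: float | None = None
    homolog_count: int = 0
    category: str = "Intergenic"
    variant_class: str = "SNV"
    context: str = "NNN"
    sample_id: str = ""

    def validate(self) -> "VariantCall":
        if self.position < 1:
            raise ValidationError(f"{self.chrom}:{self.position}: position must be >= 1")
        if self.tumor_alt > self.tumor_depth:
            raise ValidationError(
                f"{self.chrom}:{self.position}: tumor mutant reads "
                f"{self.tumor_alt} exceed depth {self.tumor_depth}"
            )
        if self.germline_alt > self.germline_depth:
            raise ValidationError(
                f"{self.chrom}:{self.position}: germline mutant reads "
                f"{self.germline_alt} exceed depth {self.germline_depth}"
            )
        if self.alt_forward + self.alt_reverse != self.tumor_alt:
            raise ValidationError(
                f"{self.chrom}:{self.position}: forward+reverse mutant reads "
                f"({self.alt_forward}+{self.alt_reverse}) != tumor mutant reads {self.tumor_alt}"
            )
        if self.category not in ANNOTATION_CATEGORIES:
            raise ValidationError(
                f"{self.chrom}:{self.position}: unknown annotation category {self.category!r}"
            )
        if self.variant_class not in ("SNV", "indel"):
            raise ValidationError(f"variant class must be SNV or indel, got {self.variant_class!r}")
        if self.somatic_score < 0:
            raise ValidationError("somatic score must be non-negative")
        return self

    @property
    def tumor_vaf(self) -> float:
        """Tumor variant allele fraction (mutant reads / depth)."""
        if self.tumor_depth == 0:
            raise ValidationError(f"{self.chrom}:{self.position}: zero tumor depth")
        return self.tumor_alt / self.tumor_depth


@dataclass
class Segment:
    """A copy-number segment: 0-based half-open interval with log2 ratio."""

    chrom: str
    start: int
    end: int
    log2: float
    copy_number: int | None = None
    loh: bool = False
    sample_id: str = ""

    def validate(self) -> "Segment":
        if self.end <= self.start:
            raise ValidationError(
                f"{self.chrom}:{self.start}-{self.end}: segment end must exceed start"
            )
        if self.start < 0:
            raise ValidationError("segment start must be >= 0")
        return self

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position_1based: int) -> bool:
        return self.start < position_1based <= self.end


@dataclass
class SVEvent:
    """A structural variant: an ordered pair of breakpoints and a type label."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    sv_type: str = "deletion"
    sample_id: str = ""

    def canonical(self, layout: GenomeLayout | None = None) -> "SVEvent":
        """Return a copy with breakpoints in canonical (A <= B) order."""
        key_a = (self.chrom_a if layout is None else layout.rank(self.chrom_a), self.pos_a)
        key_b = (self.chrom_b if layout is None else layout.rank(self.chrom_b), self.pos_b)
        if key_b < key_a:
            return dataclasses.replace(
                self, chrom_a=self.chrom_b, pos_a=self.pos_b, chrom_b=self.chrom_a, pos_b=self.pos_a
            )
        return dataclasses.replace(self)


@dataclass(frozen=True)
class SampleProfile:
    """Per-sample purity and mean ploidy."""

    sample_id: str
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValidationError(f"purity {self.purity} outside [0, 1]")
        if self.ploidy <= 0:
            raise ValidationError("ploidy must be positive")


@dataclass
class GeneModel:
    """A gene's covered footprint: merged intervals and their total length."""

    name: str
    intervals: tuple[tuple[str, int, int], ...]
    covered_bases: int = -1

    def __post_init__(self) -> None:
        merged = merge_intervals(self.intervals)
        object.__setattr__(self, "intervals", merged)
        total = sum(e - s for _, s, e in merged)
        if self.covered_bases < 0:
            self.covered_bases = total
        elif self.covered_bases != total:
            raise ValidationError(
                f"gene {self.name}: covered bases {self.covered_bases} != merged interval length {total}"
            )

    def span(self) -> tuple[str, int, int]:
        """Overall (chrom, start, end) span; genes are single-chromosome here."""
        chroms = {c for c, _, _ in self.intervals}
        if len(chroms) != 1:
            raise ValidationError(f"gene {self.name} spans multiple chromosomes")
        return (
            next(iter(chroms)),
            min(s for _, s, _ in self.intervals),
            max(e for _, _, e in self.intervals),
        )


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> tuple[tuple[str, int, int], ...]:
    """Merge overlapping/abutting half-open intervals per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for chrom, start, end in intervals:
        if end <= start:
            raise ValidationError(f"{chrom}:{start}-{end}: empty interval")
        if chrom not in by_chrom:
            by_chrom[chrom] = []
            order.append(chrom)
        by_chrom[chrom].append((start, end))
    out: list[tuple[str, int, int]] = []
    for chrom in order:
        merged: list[list[int]] = []
        for start, end in sorted(by_chrom[chrom]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        out.extend((chrom, s, e) for s, e in merged)
    return tuple(out)


# ---------------------------------------------------------------------------
# coordinate conversions (centralised so the convention lives in one place)
# ---------------------------------------------------------------------------


def pos_to_interval(position_1based: int) -> tuple[int, int]:
    """1-based point position -> 0-based half-open single-base interval."""
    return position_1based - 1, position_1based


def interval_to_pos(start: int, end: int) -> int:
    """Inverse of :func:`pos_to_interval` for a single-base interval."""
    if end != start + 1:
        raise ValidationError("not a single-base interval")
    return start + 1


# ---------------------------------------------------------------------------
# variant I/O: VCF 4.2 via pysam, plus a documented TSV dialect
# ---------------------------------------------------------------------------

_VCF_INFO = [
    ("SSC", "1", "Float", "Somatic score"),
    ("FS", "1", "Float", "Phred-scaled Fisher strand bias"),
    ("HOMCNT", "1", "Integer", "Count of highly homologous regions around the site"),
    ("DBMAF", "1", "Float", "dbSNP minor allele frequency when catalogued"),
    ("ANN", "1", "String", "Functional annotation category"),
    ("VC", "1", "String", "Variant class (SNV or indel)"),
    ("CTX", "1", "String", "Trinucleotide context"),
    ("MBQ", ".", "Integer", "Base qualities of tumor mutant reads"),
]

_VCF_FORMAT = [
    ("DP", "1", "Integer", "Read depth"),
    ("AD", "R", "Integer", "Allelic depths (ref, alt)"),
    ("ALTF", "1", "Integer", "Alt-supporting reads on the forward strand"),
    ("ALTR", "1", "Integer", "Alt-supporting reads on the reverse strand"),
]

_TSV_COLUMNS = [
    "sample_id", "chrom", "position", "ref", "alt", "tumor_depth", "tumor_alt",
    "germline_depth", "germline_alt", "somatic_score", "bq_mutant", "alt_forward",
    "alt_reverse", "strand_bias", "dbsnp_maf", "homolog_count", "category",
    "variant_class", "context",
]


def _vcf_header(layout: GenomeLayout | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if layout is not None:
        for name, length in zip(layout.names, layout.lengths):
            header.contigs.add(name, length=length)
    for key, number, vtype, desc in _VCF_INFO:
        header.info.add(key, number, vtype, desc)
    for key, number, vtype, desc in _VCF_FORMAT:
        header.formats.add(key, number, vtype, desc)
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    return header


def write_variants(
    records: Sequence[VariantCall],
    path: str | Path,
    dialect: str = "vcf",
    layout: GenomeLayout | None = None,
) -> None:
    """Write variants as VCF 4.2 (dialect ``"vcf"``) or tab-delimited (``"tsv"``).

    The TSV dialect is a plain header+rows table carrying every
    :class:`VariantCall` field (base qualities comma-joined); it exists so
    desk-scale fixtures stay human-readable and diffable.
    """
    path = Path(path)
    for rec in records:
        rec.validate()
    if dialect == "tsv":
        rows = []
        for rec in records:
            row = {c: getattr(rec, c) for c in _TSV_COLUMNS if c not in ("bq_mutant", "dbsnp_maf")}
            row["bq_mutant"] = ",".join(str(q) for q in rec.bq_mutant)
            row["dbsnp_maf"] = "" if rec.dbsnp_maf is None else rec.dbsnp_maf
            rows.append(row)
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if dialect != "vcf":
        raise FormatError(f"unknown variant dialect {dialect!r}")
    if layout is None:
        layout = _layout_from_records(records)
    header = _vcf_header(layout)
    try:
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for rec in records:
                row = out.new_record(
                    contig=rec.chrom,
                    start=rec.position - 1,
                    stop=rec.position - 1 + len(rec.ref),
                    alleles=(rec.ref, rec.alt),
                )
                row.info["SSC"] = float(rec.somatic_score)
                row.info["FS"] = float(rec.strand_bias)
                row.info["HOMCNT"] = int(rec.homolog_count)
                if rec.dbsnp_maf is not None:
                    row.info["DBMAF"] = float(rec.dbsnp_maf)
                row.info["ANN"] = rec.category.replace(" ", "_")
                row.info["VC"] = rec.variant_class
                row.info["CTX"] = rec.context
                if rec.bq_mutant:
                    row.info["MBQ"] = tuple(int(q) for q in rec.bq_mutant)
                row.samples["TUMOR"]["DP"] = rec.tumor_depth
                row.samples["TUMOR"]["AD"] = (rec.tumor_depth - rec.tumor_alt, rec.tumor_alt)
                row.samples["TUMOR"]["ALTF"] = rec.alt_forward
                row.samples["TUMOR"]["ALTR"] = rec.alt_reverse
                row.samples["NORMAL"]["DP"] = rec.germline_depth
                row.samples["NORMAL"]["AD"] = (
                    rec.germline_depth - rec.germline_alt,
                    rec.germline_alt,
                )
                out.write(row)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def _layout_from_records(records: Sequence[VariantCall]) -> GenomeLayout:
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.chrom] = max(seen.get(rec.chrom, 0), rec.position + len(rec.ref))
    if not seen:
        seen = {"chr1": 1}
    return GenomeLayout.from_dict(seen)


def read_variants(
    path: str | Path, dialect: str = "vcf", sample_id: str = ""
) -> list[VariantCall]:
    """Read variants from VCF or the package TSV dialect.

    Multi-allelic VCF records are split into biallelic records, one per
    alternate allele.  VCF INFO floats are stored in 32-bit precision, so
    score fields are rounded (4 decimals; 6 for dbSNP MAF) on read — the
    TSV dialect is fully lossless.  Malformed records raise :class:`FormatError` naming
    the record; invariant violations raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect != "vcf":
        raise FormatError(f"unknown variant dialect {dialect!r}")
    out: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        if "TUMOR" not in list(vcf.header.samples) or "NORMAL" not in list(vcf.header.samples):
            raise FormatError(f"{path}: expected TUMOR and NORMAL sample columns")
        for i, row in enumerate(vcf, start=1):
            alts = row.alts or ()
            for alt in alts:
                try:
                    tumor = row.samples["TUMOR"]
                    normal = row.samples["NORMAL"]
                    if tumor.get("AD") is None or tumor.get("DP") is None:
                        raise FormatError(
                            f"{path} record {i}: missing required depth field AD/DP in TUMOR"
                        )
                    if normal.get("AD") is None or normal.get("DP") is None:
                        raise FormatError(
                            f"{path} record {i}: missing required depth field AD/DP in NORMAL"
                        )
                    info = row.info
                    rec = VariantCall(
                        chrom=row.chrom,
                        position=row.pos,
                        ref=row.ref,
                        alt=alt,
                        tumor_depth=int(tumor["DP"]),
                        tumor_alt=int(tumor["AD"][1]),
                        germline_depth=int(normal["DP"]),
                        germline_alt=int(normal["AD"][1]),
                        somatic_score=round(float(info.get("SSC", 0.0)), 4),
                        bq_mutant=tuple(int(q) for q in info.get("MBQ", ())),
                        alt_forward=int(tumor.get("ALTF", 0)),
                        alt_reverse=int(tumor.get("ALTR", 0)),
                        strand_bias=round(float(info.get("FS", 0.0)), 4),
                        dbsnp_maf=(
                            round(float(info["DBMAF"]), 6) if "DBMAF" in info else None
                        ),
                        homolog_count=int(info.get("HOMCNT", 0)),
                        category=str(info.get("ANN", "Intergenic")).replace("_", " "),
                        variant_class=str(info.get("VC", "SNV")),
                        context=str(info.get("CTX", "NNN")),
                        sample_id=sample_id,
                    ).validate()
                except ValidationError as exc:
                    raise ValidationError(f"{path} record {i}: {exc}") from exc
                out.append(rec)
    return out


def _read_variants_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            out.append(
                VariantCall(
                    chrom=row.chrom,
                    position=int(row.position),
                    ref=row.ref,
                    alt=row.alt,
                    tumor_depth=int(row.tumor_depth),
                    tumor_alt=int(row.tumor_alt),
                    germline_depth=int(row.germline_depth),
                    germline_alt=int(row.germline_alt),
                    somatic_score=float(row.somatic_score),
                    bq_mutant=tuple(
                        int(q) for q in str(row.bq_mutant).split(",") if q != ""
                    ),
                    alt_forward=int(row.alt_forward),
                    alt_reverse=int(row.alt_reverse),
                    strand_bias=float(row.strand_bias),
                    dbsnp_maf=None if row.dbsnp_maf == "" else float(row.dbsnp_maf),
                    homolog_count=int(row.homolog_count),
                    category=row.category,
                    variant_class=row.variant_class,
                    context=row.context,
                    sample_id=row.sample_id,
                ).validate()
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# segment I/O (SEG with an LOH column extension)
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "num_probes", "log2", "cn", "loh"]


def write_segments(segments: Sequence[Segment], path: str | Path) -> None:
    rows = []
    for seg in segments:
        seg.validate()
        rows.append(
            {
                "sample_id": seg.sample_id,
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "num_probes": max(1, seg.length // 1000),
                "log2": seg.log2,
                "cn": "" if seg.copy_number is None else seg.copy_number,
                "loh": int(seg.loh),
            }
        )
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(Path(path), sep="\t", index=False)


def read_segments(path: str | Path) -> list[Segment]:
    """Read a SEG-style table; validates per-sample non-overlap."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("sample_id", "chrom", "start", "end", "log2") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segments.append(
                Segment(
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    log2=float(row.log2),
                    copy_number=(
                        int(row.cn) if "cn" in df.columns and row.cn != "" else None
                    ),
                    loh=bool(int(row.loh)) if "loh" in df.columns else False,
                    sample_id=row.sample_id,
                ).validate()
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    validate_non_overlapping(segments)
    return segments


def validate_non_overlapping(segments: Sequence[Segment]) -> None:
    """Raise if two segments of one sample on one chromosome overlap."""
    by_key: dict[tuple[str, str], list[Segment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping segments for sample {sample!r} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


# ---------------------------------------------------------------------------
# SV (BEDPE) and gene (BED) I/O
# ---------------------------------------------------------------------------


def write_svs(svs: Sequence[SVEvent], path: str | Path) -> None:
    rows = [
        {
            "chrom1": sv.chrom_a, "start1": sv.pos_a - 1, "end1": sv.pos_a,
            "chrom2": sv.chrom_b, "start2": sv.pos_b - 1, "end2": sv.pos_b,
            "name": sv.sv_type, "score": ".", "strand1": "+", "strand2": "+",
            "sample_id": sv.sample_id,
        }
        for sv in svs
    ]
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "strand1", "strand2", "sample_id"]
    pd.DataFrame(rows, columns=cols).to_csv(Path(path), sep="\t", index=False)


def read_svs(path: str | Path) -> list[SVEvent]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["chrom1", "start1", "chrom2", "start2"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [
        SVEvent(
            chrom_a=row.chrom1,
            pos_a=int(row.start1) + 1,
            chrom_b=row.chrom2,
            pos_b=int(row.start2) + 1,
            sv_type=getattr(row, "name", "deletion") or "deletion",
            sample_id=getattr(row, "sample_id", ""),
        )
        for row in df.itertuples(index=False)
    ]


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read BED6 gene intervals; rows sharing a name merge into one gene."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    by_gene: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path} line {i}: BED needs >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            by_gene.setdefault(name, []).append((chrom, start, end))
    return [GeneModel(name=name, intervals=tuple(ivals)) for name, ivals in by_gene.items()]


def write_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write tabular results as TSV (the package's uniform results format)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    try:
        df.to_csv(Path(path), sep="\t", index=False)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


#: Default desk-scale mini-genome: three 50 Mb chromosomes.
DEFAULT_LAYOUT = GenomeLayout(("chr1", "chr2", "chr3"), (50_000_000,) * 3)
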