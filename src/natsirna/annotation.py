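"""Gene/transcript annotation models and I/O.

Internal coordinates are 0-based half-open ``[start, end)``; GFF3/GTF at the
file boundary are 1-based inclusive and converted on read/write.  A
:class:`TranscriptModel` is a stranded, exon-structured gene model; an
:class:`AnnotationSet` indexes models per chromosome for overlap queries.

Gene models derived from coding sequence alone (no untranslated regions) can
be extended with assembled transcripts via :func:`extend_with_assembly`,
which picks the longest same-strand overlapping assembly for each model —
the UTR-extension step that precedes antisense-overlap detection.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "MirnaPlacement",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "extend_with_assembly",
    "place_mirna",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation input (parse or coordinate errors)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise AnnotationError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise AnnotationError(
                f"end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Length of the overlap with *other* (0 if disjoint or other chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """A transcript with its exon structure.

    ``provenance`` records whether the span comes from the CDS-only gene
    model or was replaced by a UTR-extended assembled transcript.
    """

    transcript_id: str
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "coding"  # coding | pre_miRNA
    provenance: str = "cds_only"  # cds_only | utr_extended

    def __post_init__(self) -> None:
        if not self.exons:
            self.exons = [self.span]
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.span.chrom or e.strand != self.span.strand:
                raise AnnotationError(
                    f"{self.transcript_id}: exon chrom/strand differs from span"
                )
            if prev_end is not None and e.start < prev_end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e.end
        if (
            self.exons[0].start != self.span.start
            or self.exons[-1].end != self.span.end
        ):
            raise AnnotationError(
                f"{self.transcript_id}: span does not match exon extent"
            )

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in coordinate order."""
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(
                    GenomicInterval(self.chrom, left.end, right.start, self.strand)
                )
        return out


@dataclass
class MirnaPlacement:
    """Placement of a pre-miRNA locus relative to host transcripts."""

    mirna_id: str
    host_gene_id: Optional[str]
    placement: str  # intergenic | intronic | exon_overlapping
    intron_ordinal: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.placement == "intronic") != (self.intron_ordinal is not None):
            raise AnnotationError("intron_ordinal set iff placement is intronic")


class AnnotationSet:
    """A collection of transcript models with a per-chromosome index.

    Gene ids are unique within the set.  Overlap queries use a sorted
    start-coordinate index with a running maximum end, adequate for the
    annotation sizes this pipeline handles.
    """

    def __init__(self, models: Iterable[TranscriptModel] = ()):
        self._models: dict[str, TranscriptModel] = {}
        self._index: dict[str, tuple[list[int], list[TranscriptModel]]] = {}
        self._dirty = False
        for m in models:
            self.add(m)

    def add(self, model: TranscriptModel) -> None:
        if model.gene_id in self._models:
            raise AnnotationError(f"duplicate gene_id: {model.gene_id}")
        self._models[model.gene_id] = model
        self._dirty = True

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._models.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __getitem__(self, gene_id: str) -> TranscriptModel:
        return self._models[gene_id]

    def chromosomes(self) -> set[str]:
        return {m.chrom for m in self}

    def _build_index(self) -> None:
        by_chrom: dict[str, list[TranscriptModel]] = {}
        for m in self._models.values():
            by_chrom.setdefault(m.chrom, []).append(m)
        self._index = {}
        for chrom, ms in by_chrom.items():
            ms.sort(key=lambda m: (m.span.start, m.span.end, m.gene_id))
            self._index[chrom] = ([m.span.start for m in ms], ms)
        self._dirty = False

    def overlapping(
        self, interval: GenomicInterval, strand: Optional[str] = None
    ) -> list[TranscriptModel]:
        """Models whose span overlaps *interval* by >= 1 nt.

        ``strand`` restricts to one strand; ``None`` returns both.
        """
        if self._dirty:
            self._build_index()
        entry = self._index.get(interval.chrom)
        if entry is None:
            return []
        starts, ms = entry
        hi = bisect.bisect_left(starts, interval.end)
        out = []
        for m in ms[:hi]:
            if m.span.end > interval.start and (
                strand is None or m.strand == strand
            ):
                out.append(m)
        return out


# ---------------------------------------------------------------------------
# Readers / writers

_GFF_DIALECTS = ("gff3", "gtf", "bed")


def read_annotation(
    path: str | Path,
    dialect: str = "gff3",
    pre_mirna_types: tuple[str, ...] = ("pre_miRNA", "miRNA_primary_transcript"),
) -> AnnotationSet:
    """Read an annotation file into an :class:`AnnotationSet`.

    GFF3/GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Multi-exon records sharing a transcript id
    are grouped into one model; records with strand ``.`` are rejected.
    Features whose type is in ``pre_mirna_types`` become ``pre_miRNA`` models.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"no such file: {path}")
    if dialect not in _GFF_DIALECTS:
        raise AnnotationError(f"unknown dialect {dialect!r}; expected {_GFF_DIALECTS}")
    if dialect == "bed":
        return _read_bed6(path)
    return _read_gff(path, dialect, pre_mirna_types)


def _read_gff(
    path: Path, dialect: str, pre_mirna_types: tuple[str, ...]
) -> AnnotationSet:
    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    exon_groups: dict[str, list[gffutils.Feature]] = {}
    standalone: list[gffutils.Feature] = []
    parent_meta: dict[str, gffutils.Feature] = {}

    for feat in db.all_features():
        if feat.featuretype == "exon":
            tid = _transcript_id_of(feat, dialect)
            exon_groups.setdefault(tid, []).append(feat)
        elif feat.featuretype in pre_mirna_types:
            standalone.append(feat)
        elif feat.featuretype in ("mRNA", "transcript", "gene", "CDS"):
            tid = _own_id_of(feat, dialect)
            parent_meta.setdefault(tid, feat)

    out = AnnotationSet()
    seen_tids = set()
    for tid, feats in exon_groups.items():
        exons = [_to_interval(f) for f in feats]
        chrom, strand = exons[0].chrom, exons[0].strand
        exons.sort(key=lambda e: e.start)
        span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        gene_id = tid
        meta = parent_meta.get(tid)
        if meta is not None:
            gene_id = _gene_id_of(meta, dialect) or tid
        else:
            gene_id = _gene_id_from_exon(feats[0], dialect) or tid
        out.add(TranscriptModel(tid, gene_id, span, exons))
        seen_tids.add(tid)

    # parent features without exon children become single-exon models
    for tid, feat in parent_meta.items():
        if tid in seen_tids or any(tid == m.transcript_id for m in out):
            continue
        iv = _to_interval(feat)
        gid = _gene_id_of(feat, dialect) or tid
        if gid in out:
            continue
        out.add(TranscriptModel(tid, gid, iv))

    for feat in standalone:
        iv = _to_interval(feat)
        mid = _own_id_of(feat, dialect)
        out.add(TranscriptModel(mid, mid, iv, biotype="pre_miRNA"))
    return out


def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >= 8 tab-separated fields"
                )
            if fields[6] not in ("+", "-"):
                raise AnnotationError(
                    f"{path}:{lineno}: unstranded or invalid strand {fields[6]!r}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: end {end} < start {start}"
                )


def _to_interval(feat: gffutils.Feature) -> GenomicInterval:
    # gffutils keeps 1-based inclusive; convert to 0-based half-open
    return GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)


def _attr_first(feat: gffutils.Feature, key: str) -> Optional[str]:
    vals = feat.attributes.get(key)
    return vals[0] if vals else None


def _transcript_id_of(feat: gffutils.Feature, dialect: str) -> str:
    if dialect == "gtf":
        tid = _attr_first(feat, "transcript_id")
    else:
        tid = _attr_first(feat, "Parent")
    if tid is None:
        raise AnnotationError(
            f"exon at {feat.seqid}:{feat.start} lacks a transcript link"
        )
    return tid


def _own_id_of(feat: gffutils.Feature, dialect: str) -> str:
    if dialect == "gtf":
        return (
            _attr_first(feat, "transcript_id")
            or _attr_first(feat, "gene_id")
            or feat.id
        )
    return _attr_first(feat, "ID") or feat.id


def _gene_id_of(feat: gffutils.Feature, dialect: str) -> Optional[str]:
    if dialect == "gtf":
        return _attr_first(feat, "gene_id")
    return _attr_first(feat, "gene_id") or _attr_first(feat, "Parent")


def _gene_id_from_exon(feat: gffutils.Feature, dialect: str) -> Optional[str]:
    return _attr_first(feat, "gene_id")


def _read_bed6(path: Path) -> AnnotationSet:
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"{path}:{lineno}: BED6 needs 6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"{path}:{lineno}: unstranded BED record {name!r}"
                )
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            out.add(TranscriptModel(name, name, iv))
    return out


def write_annotation(
    annotations: AnnotationSet, path: str | Path, dialect: str = "gff3"
) -> None:
    """Write models as GFF3 (mRNA/pre_miRNA + exon lines) or BED6 spans."""
    path = Path(path)
    if dialect == "bed":
        with open(path, "w") as fh:
            for m in sorted(annotations, key=lambda m: (m.chrom, m.span.start)):
                fh.write(
                    f"{m.chrom}\t{m.span.start}\t{m.span.end}\t{m.gene_id}\t0\t{m.strand}\n"
                )
        return
    if dialect != "gff3":
        raise AnnotationError(f"cannot write dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(annotations, key=lambda m: (m.chrom, m.span.start, m.gene_id)):
            ftype = "pre_miRNA" if m.biotype == "pre_miRNA" else "mRNA"
            attrs = f"ID={m.transcript_id};gene_id={m.gene_id}"
            fh.write(
                f"{m.chrom}\tnatsirna\t{ftype}\t{m.span.start + 1}\t{m.span.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            if m.biotype == "pre_miRNA":
                continue
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\tnatsirna\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\tParent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# UTR extension

def extend_with_assembly(
    cds_models: AnnotationSet, assembled: AnnotationSet
) -> AnnotationSet:
    """Extend CDS-only gene models with assembled transcripts.

    Each assembled transcript is linked to the same-strand CDS model with the
    largest span overlap (ties break to the lexicographically smaller
    gene_id).  For each CDS model the longest linked transcript replaces the
    model's exon structure; the span is widened to the hull of the CDS span
    and the assembly, so extension never shortens a model.  Models with no
    overlapping assembly pass through unchanged (``provenance='cds_only'``).
    """
    missing = assembled.chromosomes() - cds_models.chromosomes()
    if missing:
        warnings.warn(
            f"assembled transcripts on chromosomes absent from CDS models: "
            f"{sorted(missing)}",
            stacklevel=2,
        )

    linked: dict[str, list[TranscriptModel]] = {}
    for asm in assembled:
        candidates = cds_models.overlapping(asm.span, strand=asm.strand)
        if not candidates:
            continue
        best = max(
            candidates,
            key=lambda m: (m.span.overlap_length(asm.span), _neg_lex(m.gene_id)),
        )
        linked.setdefault(best.gene_id, []).append(asm)

    out = AnnotationSet()
    for model in cds_models:
        asms = linked.get(model.gene_id)
        if not asms:
            out.add(model)
            continue
        chosen = max(asms, key=lambda a: (a.span.length(), _neg_lex(a.transcript_id)))
        new_start = min(model.span.start, chosen.span.start)
        new_end = max(model.span.end, chosen.span.end)
        exons = [replace(e, strand=model.strand) for e in chosen.exons]
        # widen terminal exons so the hull still covers the original CDS span
        exons[0] = replace(exons[0], start=min(exons[0].start, new_start))
        exons[-1] = replace(exons[-1], end=max(exons[-1].end, new_end))
        span = GenomicInterval(model.chrom, new_start, new_end, model.strand)
        out.add(
            TranscriptModel(
                model.transcript_id,
                model.gene_id,
                span,
                exons,
                biotype=model.biotype,
                provenance="utr_extended",
            )
        )
    return out


class _neg_lex(str):
    """Reverse lexicographic comparison, for max() with smaller-id tie-break."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# pre-miRNA placement

def place_mirna(mirna: TranscriptModel, hosts: AnnotationSet) -> MirnaPlacement:
    """Classify a pre-miRNA locus as intronic, exon-overlapping or intergenic.

    Intronic: fully contained in one intron of a same-strand host, with the
    intron counted 1-based in transcription order (reverse coordinate order
    on the minus strand).  Exon-overlapping: overlaps any host exon on either
    strand.  Otherwise intergenic.  Classes are mutually exclusive; intronic
    takes precedence.
    """
    if mirna.biotype != "pre_miRNA":
        raise AnnotationError(f"{mirna.transcript_id} is not a pre_miRNA model")
    span = mirna.span
    for host in hosts.overlapping(span):
        if host.biotype == "pre_miRNA" or host.strand != span.strand:
            continue
        introns = host.introns()
        for i, intron in enumerate(introns):
            if intron.contains(span):
                ordinal = i + 1 if host.strand == "+" else len(introns) - i
                return MirnaPlacement(
                    mirna.transcript_id, host.gene_id, "intronic", ordinal
                )
    for host in hosts.overlapping(span):
        if host.biotype == "pre_miRNA":
            continue
        for exon in host.exons:
            if exon.overlap_length(span) >= 1:
                return MirnaPlacement(
                    mirna.transcript_id, host.gene_id, "exon_overlapping"
                )
    return MirnaPlacement(mirna.transcript_id, None, "intergenic")
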