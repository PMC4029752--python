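"""Small-RNA tag handling and nat-siRNA quantification.

Tags are unique small-RNA sequences carrying per-library raw counts and
genomic placements.  A tag becomes a nat-siRNA candidate for a cis-NAT pair
when its alignment (i) has zero mismatches, (ii) is 20-28 nt long, (iii)
lies fully inside the pair's overlap region, and (iv) reaches at least
5 reads per 10 million (RP10M) in at least one library.  Forward-strand and
reverse-strand read totals (FR, RR) per pair feed the strand-bias test.

Abundances are normalized to RP10M: raw count * 1e7 / library total mapped
reads.  A multi-mapping tag contributes its full count to every overlap it
maps into; no fractional allocation is attempted.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .annotation import GenomicInterval
from .pairs import CisNatPair
from .stats import rp10m

__all__ = [
    "SrnaLibrary",
    "SrnaTag",
    "NatSirnaAssignment",
    "rp10m",
    "load_tags_tsv",
    "load_tags_fasta",
    "load_alignments_tsv",
    "load_alignments_sam",
    "assign_tags",
    "pair_strand_totals",
    "length_distribution",
    "first_nt_distribution",
]

# parsing window applied to tags at load time
MIN_TAG_LEN = 17
MAX_TAG_LEN = 36


@dataclass(frozen=True)
class SrnaLibrary:
    """One sequencing library: condition label, replicate, and the total
    mapped read count used as the normalization denominator."""

    name: str
    condition: str
    replicate: int
    total_reads: float

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"library {self.name}: total_reads must be > 0")


@dataclass
class SrnaTag:
    """A unique small-RNA sequence with counts and genomic placements."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    alignments: list[tuple[GenomicInterval, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not set(self.sequence) <= set("ACGT"):
            raise ValueError(f"invalid nucleotides in tag {self.sequence!r}")
        if not (MIN_TAG_LEN <= len(self.sequence) <= MAX_TAG_LEN):
            raise ValueError(
                f"tag length {len(self.sequence)} outside the "
                f"{MIN_TAG_LEN}-{MAX_TAG_LEN} nt parsing window"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def first_nt(self) -> str:
        return self.sequence[0]

    def total_count(self, libraries: Optional[Iterable[str]] = None) -> int:
        keys = self.counts.keys() if libraries is None else libraries
        return sum(self.counts.get(k, 0) for k in keys)


@dataclass(frozen=True)
class NatSirnaAssignment:
    """A retained (pair, tag, alignment) triple."""

    pair_id: str
    tag: SrnaTag
    alignment: GenomicInterval
    aligned_strand: str
    within_overlap: bool = True


# ---------------------------------------------------------------------------
# Input formats

def load_tags_tsv(path: str | Path) -> list[SrnaTag]:
    """TSV with a ``sequence`` column and one raw-count column per library."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing 'sequence' column")
    libs = [c for c in df.columns if c != "sequence"]
    tags = []
    for row in df.itertuples(index=False):
        counts = {
            lib: int(getattr(row, lib)) for lib in libs if int(getattr(row, lib)) > 0
        }
        tags.append(SrnaTag(row.sequence, counts))
    return tags


def load_tags_fasta(path: str | Path, library: str) -> list[SrnaTag]:
    """FASTA with the raw count appended to the header as ``id_N``."""
    tags = []
    header: Optional[str] = None
    seq_parts: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        try:
            count = int(header.rsplit("_", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}: header {header!r} lacks the '_N' count suffix"
            ) from exc
        tags.append(SrnaTag("".join(seq_parts), {library: count}))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0]
                seq_parts = []
            else:
                seq_parts.append(line)
    _flush()
    return tags


def load_alignments_tsv(
    path: str | Path, tags: Sequence[SrnaTag]
) -> list[SrnaTag]:
    """Attach alignments from a TSV (sequence, chrom, start0, strand,
    mismatches) to the matching tags; returns the tags that aligned."""
    by_seq = {t.sequence: t for t in tags}
    df = pd.read_csv(
        path,
        sep="\t",
        names=["sequence", "chrom", "start0", "strand", "mismatches"],
        header=0,
        dtype={"sequence": str, "chrom": str, "strand": str},
    )
    hit: dict[str, SrnaTag] = {}
    for row in df.itertuples(index=False):
        tag = by_seq.get(str(row.sequence).upper().replace("U", "T"))
        if tag is None:
            continue
        iv = GenomicInterval(
            row.chrom, int(row.start0), int(row.start0) + tag.length, row.strand
        )
        tag.alignments.append((iv, int(row.mismatches)))
        hit[tag.sequence] = tag
    return list(hit.values())


def load_alignments_sam(path: str | Path, tags: Sequence[SrnaTag]) -> list[SrnaTag]:
    """Attach alignments from a SAM/BAM file (tag sequence = read sequence;
    mismatches from the NM tag, 0 when absent)."""
    by_seq = {t.sequence: t for t in tags}
    hit: dict[str, SrnaTag] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            seq = rec.query_sequence.upper()
            if rec.is_reverse:
                seq = _revcomp(seq)
            tag = by_seq.get(seq)
            if tag is None:
                continue
            strand = "-" if rec.is_reverse else "+"
            iv = GenomicInterval(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            tag.alignments.append((iv, int(nm)))
            hit[tag.sequence] = tag
    return list(hit.values())


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Assignment and summaries

def assign_tags(
    pairs: Sequence[CisNatPair],
    tags: Sequence[SrnaTag],
    libraries: Sequence[SrnaLibrary],
    min_rp10m: float = 5.0,
    min_len: int = 20,
    max_len: int = 28,
    require_containment: bool = True,
) -> list[NatSirnaAssignment]:
    """Assign tags to cis-NAT overlap regions under the nat-siRNA filters.

    A (pair, tag, alignment) triple is retained iff the alignment has zero
    mismatches, the tag is ``min_len``-``max_len`` nt, the alignment lies
    fully inside the overlap (or merely overlaps it when
    ``require_containment`` is false), and the tag reaches ``min_rp10m``
    normalized reads in at least one library.
    """
    lib_by_name = {l.name: l for l in libraries}

    def _abundant(tag: SrnaTag) -> bool:
        for name, count in tag.counts.items():
            lib = lib_by_name.get(name)
            if lib is not None and rp10m(count, lib.total_reads) >= min_rp10m:
                return True
        return False

    # index qualifying alignments per chromosome, sorted by start
    aln_index: dict[str, list[tuple[int, int, str, SrnaTag]]] = {}
    for tag in tags:
        if not (min_len <= tag.length <= max_len):
            continue
        if not _abundant(tag):
            continue
        for iv, mism in tag.alignments:
            if mism != 0:
                continue
            aln_index.setdefault(iv.chrom, []).append(
                (iv.start, iv.end, iv.strand, tag)
            )
    for rows in aln_index.values():
        rows.sort(key=lambda r: r[0])

    out: list[NatSirnaAssignment] = []
    for pair in pairs:
        ov = pair.overlap
        rows = aln_index.get(ov.chrom, [])
        starts = [r[0] for r in rows]
        lo = 0 if not require_containment else bisect.bisect_left(starts, ov.start)
        hi = bisect.bisect_left(starts, ov.end)
        for start, end, strand, tag in rows[lo:hi]:
            if require_containment:
                if start < ov.start or end > ov.end:
                    continue
                contained = True
            else:
                if end <= ov.start:
                    continue
                contained = ov.start <= start and end <= ov.end
            out.append(
                NatSirnaAssignment(pair.id, tag, GenomicInterval(
                    ov.chrom, start, end, strand
                ), strand, contained)
            )
    return out


def pair_strand_totals(
    assignments: Iterable[NatSirnaAssignment],
    library: SrnaLibrary,
    pair_id: Optional[str] = None,
) -> dict[str, tuple[int, int]] | tuple[int, int]:
    """Forward/reverse raw read totals (FR, RR) per pair for one library.

    Each unique tag contributes its raw library count once per strand per
    pair, regardless of how many alignments it has inside the overlap.
    Returns a dict keyed by pair id, or a single (FR, RR) tuple when
    ``pair_id`` is given.
    """
    seen: set[tuple[str, str, str]] = set()
    totals: dict[str, list[int]] = {}
    for a in assignments:
        key = (a.pair_id, a.tag.sequence, a.aligned_strand)
        if key in seen:
            continue
        seen.add(key)
        fr_rr = totals.setdefault(a.pair_id, [0, 0])
        count = a.tag.counts.get(library.name, 0)
        if a.aligned_strand == "+":
            fr_rr[0] += count
        else:
            fr_rr[1] += count
    result = {pid: (fr, rr) for pid, (fr, rr) in totals.items()}
    if pair_id is not None:
        return result.get(pair_id, (0, 0))
    return result


def _unique_tags(assignments: Iterable[NatSirnaAssignment]) -> list[SrnaTag]:
    seen: dict[str, SrnaTag] = {}
    for a in assignments:
        seen.setdefault(a.tag.sequence, a.tag)
    return list(seen.values())


def length_distribution(
    assignments: Iterable[NatSirnaAssignment], weighted: bool = False
) -> dict[int, float]:
    """Fraction of tags (or reads, when ``weighted``) per length in nt."""
    tags = _unique_tags(assignments)
    counter: Counter[int] = Counter()
    for t in tags:
        counter[t.length] += t.total_count() if weighted else 1
    total = sum(counter.values())
    return {k: v / total for k, v in sorted(counter.items())} if total else {}


def first_nt_distribution(
    assignments: Iterable[NatSirnaAssignment], weighted: bool = False
) -> dict[str, float]:
    """Fraction of tags (or reads) per 5' first nucleotide (T reported as U)."""
    tags = _unique_tags(assignments)
    counter: Counter[str] = Counter()
    for t in tags:
        nt = "U" if t.first_nt == "T" else t.first_nt
        counter[nt] += t.total_count() if weighted else 1
    total = sum(counter.values())
    return {k: v / total for k, v in sorted(counter.items())} if total else {}
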