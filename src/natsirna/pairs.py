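"""Detection and classification of cis-natural antisense transcript pairs.

A cis-NAT pair is two opposite-strand gene models on the same chromosome
whose spans overlap by more than 25 nt and by less than 2000 nt.  The
orientation of a pair is:

* ``convergent`` — the 3' ends overlap (head-to-head tails),
* ``divergent``  — the 5' ends overlap,
* ``enclosed``   — one span contains the other (tested first; boundary ties
  count as enclosed).

Pairs whose members overlap a pre-miRNA locus are excluded from the
database, because small RNAs there may come from the miRNA hairpin rather
than the antisense duplex.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .annotation import AnnotationSet, GenomicInterval, TranscriptModel

__all__ = [
    "CisNatPair",
    "find_pairs",
    "classify_orientation",
    "exclude_mirna_overlaps",
    "pair_set_union",
    "pair_id",
    "write_pairs_tsv",
    "write_pairs_bed",
    "DEFAULT_MIN_OVERLAP",
    "DEFAULT_MAX_OVERLAP",
]

# "more than 25 nt" -> >= 26; "shorter than 2000 nt" read as an overlap cap
DEFAULT_MIN_OVERLAP = 26
DEFAULT_MAX_OVERLAP = 1999


@dataclass(frozen=True)
class CisNatPair:
    """An antisense-overlapping gene pair.

    ``gene_a`` is the plus-strand member, ``gene_b`` the minus-strand member;
    ``overlap`` is the strandless shared region.
    """

    gene_a: str
    gene_b: str
    overlap: GenomicInterval
    orientation: str
    mirna_excluded: bool = False
    sets: frozenset[str] = field(default_factory=frozenset)

    @property
    def id(self) -> str:
        return pair_id(self.gene_a, self.gene_b)


def pair_id(gene_a: str, gene_b: str) -> str:
    """Canonical pair identity: lexicographically smaller gene id first."""
    a, b = sorted((gene_a, gene_b))
    return f"{a}|{b}"


def classify_orientation(
    plus_span: GenomicInterval, minus_span: GenomicInterval
) -> str:
    """Orientation class of an overlapping (+, -) span pair.

    Containment (including equal boundaries) is tested first and yields
    ``enclosed``; otherwise the plus-strand gene starting first means the 3'
    ends meet (``convergent``), and the minus-strand gene starting first
    means the 5' ends meet (``divergent``).
    """
    if plus_span.overlap_length(minus_span) == 0:
        raise ValueError("spans do not overlap")
    a1, a2 = plus_span.start, plus_span.end
    b1, b2 = minus_span.start, minus_span.end
    if (a1 <= b1 and b2 <= a2) or (b1 <= a1 and a2 <= b2):
        return "enclosed"
    if a1 < b1:
        return "convergent"
    return "divergent"


def find_pairs(
    annotations: AnnotationSet,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[CisNatPair]:
    """All opposite-strand span pairs with overlap in [min_overlap, max_overlap].

    Overlap is computed on transcript spans (UTR-extended where available);
    pre-miRNA models do not participate as pair members.  Each qualifying
    unordered pair appears exactly once.
    """
    plus: dict[str, list[TranscriptModel]] = {}
    minus: dict[str, list[TranscriptModel]] = {}
    for m in annotations:
        if m.biotype == "pre_miRNA":
            continue
        (plus if m.strand == "+" else minus).setdefault(m.chrom, []).append(m)

    out: list[CisNatPair] = []
    for chrom, plus_models in plus.items():
        minus_models = sorted(minus.get(chrom, []), key=lambda m: m.span.start)
        if not minus_models:
            continue
        starts = [m.span.start for m in minus_models]
        for pm in sorted(plus_models, key=lambda m: m.span.start):
            hi = bisect.bisect_left(starts, pm.span.end)
            for mm in minus_models[:hi]:
                ov = pm.span.overlap_length(mm.span)
                if min_overlap <= ov <= max_overlap:
                    start = max(pm.span.start, mm.span.start)
                    end = min(pm.span.end, mm.span.end)
                    out.append(
                        CisNatPair(
                            gene_a=pm.gene_id,
                            gene_b=mm.gene_id,
                            overlap=GenomicInterval(chrom, start, end),
                            orientation=classify_orientation(pm.span, mm.span),
                        )
                    )
    out.sort(key=lambda p: (p.overlap.chrom, p.overlap.start, p.id))
    return out


def exclude_mirna_overlaps(
    pairs: Iterable[CisNatPair],
    premirnas: AnnotationSet,
    annotations: AnnotationSet,
) -> tuple[list[CisNatPair], list[CisNatPair]]:
    """Drop pairs whose members overlap a pre-miRNA locus by >= 1 nt.

    Overlap with a precursor on either strand disqualifies the pair.
    Returns ``(kept, excluded)``; excluded pairs carry ``mirna_excluded=True``
    for separate reporting.
    """
    kept: list[CisNatPair] = []
    excluded: list[CisNatPair] = []
    for pair in pairs:
        hit = False
        for gid in (pair.gene_a, pair.gene_b):
            span = annotations[gid].span
            for locus in premirnas:
                if locus.span.overlap_length(span) >= 1:
                    hit = True
                    break
            if hit:
                break
        if hit:
            excluded.append(replace(pair, mirna_excluded=True))
        else:
            kept.append(pair)
    return kept, excluded


def pair_set_union(
    sets: Mapping[str, Iterable[CisNatPair]],
) -> list[CisNatPair]:
    """Union of named pair sets with per-set membership flags.

    Pair identity is the unordered gene-id pair; all sets must come from the
    same reference annotation, so a pair appearing in several sets must have
    one geometry — conflicting orientations raise ``ValueError``.
    """
    merged: dict[str, CisNatPair] = {}
    members: dict[str, set[str]] = {}
    for name, pairs in sets.items():
        for pair in pairs:
            pid = pair.id
            if pid in merged:
                if merged[pid].orientation != pair.orientation:
                    raise ValueError(
                        f"pair {pid} has conflicting orientations across sets: "
                        f"{merged[pid].orientation} vs {pair.orientation}"
                    )
            else:
                merged[pid] = pair
            members.setdefault(pid, set()).add(name)
    return [
        replace(merged[pid], sets=frozenset(members[pid]))
        for pid in sorted(merged)
    ]


def write_pairs_tsv(pairs: Iterable[CisNatPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tchrom\toverlap_start\toverlap_end\t"
            "overlap_len\torientation\tsets\n"
        )
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.overlap.chrom}\t{p.overlap.start}\t"
                f"{p.overlap.end}\t{p.overlap.length()}\t{p.orientation}\t"
                f"{','.join(sorted(p.sets))}\n"
            )


def write_pairs_bed(pairs: Iterable[CisNatPair], path: str | Path) -> None:
    """Overlap regions as BED6 (strand '.' is not allowed in our BED reader,
    so the plus strand is written; the region itself is strandless)."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.overlap.chrom}\t{p.overlap.start}\t{p.overlap.end}\t"
                f"{p.id}\t0\t+\n"
            )
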