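"""Synthetic annotation and small-RNA library generator.

Builds a fully self-contained test world: gene pairs planted in each of the
three antisense-overlap orientations, non-overlapping singleton genes,
pre-miRNA loci inside some pair members, and small-RNA tag tables whose
counts are Poisson draws around per-strand means.  Planted effects are a
forward:reverse strand ratio (strand bias) and a high-temperature fold
change applied in HT libraries, so strand-bias and differential-accumulation
callers can be validated against a machine-readable truth manifest.

What the generator emulates: the pair geometry and filtering thresholds of
a real annotation, a 21-nt length bias and 5'-adenine bias in the tags, and
Poisson sampling of counts with library-size-proportional means.  What it
does not emulate: sequencing error, overdispersion beyond Poisson, multi-
mapping tags, or exon/intron structure inside overlap regions.

Determinism: one global seed; each consumer (annotation, tag definitions,
each library's counts) draws from a named child stream, so the same seed
reproduces byte-identical outputs and adding a library does not perturb the
others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import AnnotationSet, GenomicInterval, TranscriptModel
from .pairs import pair_id

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "PlantedPair",
    "simulate_annotation",
    "simulate_srna_libraries",
    "write_tag_table",
    "write_alignments",
]

# library totals follow the four temperature-contrast sRNA datasets
# (normal vs high temperature, two replicates; ~11-15 million mapped reads)
DEFAULT_LIBRARIES: tuple[tuple[str, str, int, float], ...] = (
    ("NT1", "NT", 1, 11_250_000),
    ("HT1", "HT", 1, 14_670_000),
    ("NT2", "NT", 2, 14_610_000),
    ("HT2", "HT", 2, 12_770_000),
)

_LEN_CHOICES = np.arange(20, 29)
# 21-nt peak, echoing the observed nat-siRNA length bias
_LEN_WEIGHTS = np.array([0.08, 0.45, 0.12, 0.08, 0.12, 0.05, 0.04, 0.03, 0.03])
_NT_CHOICES = np.array(list("ACGT"))
# 5' adenine bias
_FIRST_NT_WEIGHTS = np.array([0.45, 0.18, 0.17, 0.20])


@dataclass
class SimulationConfig:
    seed: int = 0
    n_convergent: int = 6
    n_divergent: int = 2
    n_enclosed: int = 2
    n_singleton: int = 10
    n_premirna_overlapping: int = 1
    overlap_length_range: tuple[int, int] = (100, 500)
    gene_length_range: tuple[int, int] = (800, 2500)
    libraries: tuple[tuple[str, str, int, float], ...] = DEFAULT_LIBRARIES
    planted_strand_bias: float = 8.0  # FR:RR mean ratio per pair
    planted_heat_fold: float = 4.0  # HT/NT mean fold per pair
    per_strand_mean: float = 50.0  # weaker-strand mean reads at 1e7 depth
    n_tags_per_strand: int = 3
    background_tag_rate: float = 2.0  # mean tags per singleton gene
    chrom: str = "Chr1"

    def __post_init__(self) -> None:
        lo, hi = self.overlap_length_range
        if not (26 <= lo <= hi <= 1999):
            raise ValueError("overlap_length_range must lie within [26, 1999]")
        for n in (
            self.n_convergent,
            self.n_divergent,
            self.n_enclosed,
            self.n_singleton,
            self.n_premirna_overlapping,
        ):
            if n < 0:
                raise ValueError("counts must be non-negative")
        if hi >= self.gene_length_range[0]:
            raise ValueError("overlap cannot exceed the shortest gene")


@dataclass
class PlantedPair:
    gene_a: str  # plus-strand member
    gene_b: str  # minus-strand member
    orientation: str
    overlap: tuple[int, int]
    strand_bias: float
    heat_fold: float
    premirna_excluded: bool = False

    @property
    def id(self) -> str:
        return pair_id(self.gene_a, self.gene_b)

    @property
    def heat_direction(self) -> str:
        if self.heat_fold > 1:
            return "up"
        if self.heat_fold < 1:
            return "down"
        return "none"


@dataclass
class TruthManifest:
    pairs: list[PlantedPair] = field(default_factory=list)
    tag_origin: dict[str, str] = field(default_factory=dict)  # seq -> pair id / background
    chrom: str = "Chr1"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom": self.chrom,
            "pairs": [asdict(p) for p in self.pairs],
            "tag_origin": self.tag_origin,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        pairs = [
            PlantedPair(**{**p, "overlap": tuple(p["overlap"])})
            for p in payload["pairs"]
        ]
        return cls(pairs, payload["tag_origin"], payload["chrom"])


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream derived from the global seed."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Annotation

def simulate_annotation(
    config: SimulationConfig,
) -> tuple[AnnotationSet, AnnotationSet, TruthManifest]:
    """Plant gene pairs, singleton genes and pre-miRNA loci.

    Returns ``(genes, premirnas, manifest)``.  Pairs satisfy their
    orientation class and the overlap-length window by construction;
    singletons overlap nothing; the first ``n_premirna_overlapping`` pairs
    carry a ~120 nt pre-miRNA locus inside their plus-strand member.
    """
    rng = _stream(config.seed, "annotation")
    genes = AnnotationSet()
    premirnas = AnnotationSet()
    manifest = TruthManifest(chrom=config.chrom)

    cursor = 1000
    gap = 2000
    idx = 0
    orientations = (
        ["convergent"] * config.n_convergent
        + ["divergent"] * config.n_divergent
        + ["enclosed"] * config.n_enclosed
    )
    n_premirna = config.n_premirna_overlapping
    if n_premirna > len(orientations):
        raise ValueError("more pre-miRNA-overlapping pairs than pairs")

    for k, orientation in enumerate(orientations):
        ov = int(rng.integers(*config.overlap_length_range, endpoint=True))
        la = int(rng.integers(*config.gene_length_range, endpoint=True))
        lb = int(rng.integers(*config.gene_length_range, endpoint=True))
        if orientation == "enclosed":
            lb = ov  # minus member fully inside the plus member
            la = max(la, ov + 200)
            a1 = cursor
            b1 = a1 + int(rng.integers(50, la - ov - 50, endpoint=True))
        elif orientation == "convergent":
            a1 = cursor
            b1 = a1 + la - ov  # 3' ends overlap
        else:  # divergent: minus-strand gene starts first
            b1 = cursor
            a1 = b1 + lb - ov
        plus = GenomicInterval(config.chrom, a1, a1 + la, "+")
        minus = GenomicInterval(config.chrom, b1, b1 + lb, "-")
        idx += 1
        ga, gb = f"GeneP{idx:04d}", f"GeneM{idx:04d}"
        genes.add(TranscriptModel(ga + ".1", ga, plus))
        genes.add(TranscriptModel(gb + ".1", gb, minus))
        ov_start = max(plus.start, minus.start)
        ov_end = min(plus.end, minus.end)
        assert 26 <= ov_end - ov_start <= 1999

        excluded = k < n_premirna
        if excluded:
            # hairpin locus inside the plus member
            m_start = plus.start + 10
            m_end = min(m_start + 120, plus.end - 1)
            mid = f"MIR{idx:04d}"
            premirnas.add(
                TranscriptModel(
                    mid,
                    mid,
                    GenomicInterval(config.chrom, m_start, m_end, "+"),
                    biotype="pre_miRNA",
                )
            )
        manifest.pairs.append(
            PlantedPair(
                ga,
                gb,
                orientation,
                (ov_start, ov_end),
                config.planted_strand_bias,
                config.planted_heat_fold,
                premirna_excluded=excluded,
            )
        )
        cursor = max(plus.end, minus.end) + gap

    for _ in range(config.n_singleton):
        length = int(rng.integers(*config.gene_length_range, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        idx += 1
        gid = f"GeneS{idx:04d}"
        genes.add(
            TranscriptModel(
                gid + ".1",
                gid,
                GenomicInterval(config.chrom, cursor, cursor + length, strand),
            )
        )
        cursor += length + gap

    return genes, premirnas, manifest


# ---------------------------------------------------------------------------
# Small-RNA libraries

def _random_tag(rng: np.random.Generator, length: int) -> str:
    first = rng.choice(_NT_CHOICES, p=_FIRST_NT_WEIGHTS)
    rest = rng.choice(_NT_CHOICES, size=length - 1)
    return first + "".join(rest)


def simulate_srna_libraries(
    genes: AnnotationSet,
    manifest: TruthManifest,
    config: SimulationConfig,
):
    """Draw tag definitions and per-library Poisson counts.

    For each planted pair, ``n_tags_per_strand`` distinct tag loci are placed
    uniformly inside the overlap on each strand.  The minus strand carries
    the per-strand base mean; the plus strand carries base mean times the
    planted strand-bias ratio.  In HT libraries both means are multiplied by
    the planted heat fold.  Means scale with library depth (total/1e7) so a
    fold of 1 is an honest null for the count test.  Background tags land in
    singleton genes.  Returns ``(tags, libraries)`` where each tag is a dict
    with sequence, counts per library, and its single perfect alignment.
    """
    from .srna import SrnaLibrary, SrnaTag  # local import avoids cycle at doc build

    tag_rng = _stream(config.seed, "tags")
    libraries = [
        SrnaLibrary(name, cond, rep, total)
        for name, cond, rep, total in config.libraries
    ]

    # tag definitions: (sequence, interval, base_mean)
    defs: list[tuple[str, GenomicInterval, float]] = []
    seen_seqs: set[str] = set()

    def _new_tag(chrom: str, lo: int, hi: int, strand: str, mean: float, origin: str):
        length = int(tag_rng.choice(_LEN_CHOICES, p=_LEN_WEIGHTS))
        if hi - lo < length:
            length = hi - lo
        start = int(tag_rng.integers(lo, hi - length, endpoint=True))
        seq = _random_tag(tag_rng, length)
        while seq in seen_seqs:
            seq = _random_tag(tag_rng, length)
        seen_seqs.add(seq)
        defs.append((seq, GenomicInterval(chrom, start, start + length, strand), mean))
        manifest.tag_origin[seq] = origin

    for pair in manifest.pairs:
        lo, hi = pair.overlap
        minus_mean = config.per_strand_mean
        plus_mean = config.per_strand_mean * pair.strand_bias
        for strand, strand_mean in (("+", plus_mean), ("-", minus_mean)):
            per_tag = strand_mean / config.n_tags_per_strand
            for _ in range(config.n_tags_per_strand):
                _new_tag(manifest.chrom, lo, hi, strand, per_tag, pair.id)

    for model in genes:
        if not model.gene_id.startswith("GeneS"):
            continue
        n_bg = int(tag_rng.poisson(config.background_tag_rate))
        for _ in range(n_bg):
            _new_tag(
                model.chrom,
                model.span.start,
                model.span.end,
                model.strand,
                20.0,
                "background",
            )

    heat_fold_by_pair = {p.id: p.heat_fold for p in manifest.pairs}
    tags: list[SrnaTag] = []
    counts_by_lib: dict[str, np.ndarray] = {}
    for lib in libraries:
        rng = _stream(config.seed, f"library:{lib.name}")
        depth = lib.total_reads / 1e7
        means = []
        for seq, iv, base_mean in defs:
            origin = manifest.tag_origin[seq]
            fold = 1.0
            if lib.condition == "HT" and origin != "background":
                fold = heat_fold_by_pair[origin]
            means.append(base_mean * depth * fold)
        counts_by_lib[lib.name] = rng.poisson(np.asarray(means))

    for i, (seq, iv, _mean) in enumerate(defs):
        counts = {
            lib.name: int(counts_by_lib[lib.name][i])
            for lib in libraries
            if counts_by_lib[lib.name][i] > 0
        }
        tag = SrnaTag(seq, counts)
        tag.alignments.append((iv, 0))
        tags.append(tag)
    return tags, libraries


def write_tag_table(tags, libraries, path: str | Path) -> None:
    """TSV tag table: sequence + one raw-count column per library."""
    names = [lib.name for lib in libraries]
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(names) + "\n")
        for tag in tags:
            row = "\t".join(str(tag.counts.get(n, 0)) for n in names)
            fh.write(f"{tag.sequence}\t{row}\n")


def write_alignments(tags, path: str | Path) -> None:
    """TSV alignments: sequence, chrom, start0, strand, mismatches."""
    with open(path, "w") as fh:
        fh.write("sequence\tchrom\tstart0\tstrand\tmismatches\n")
        for tag in tags:
            for iv, mism in tag.alignments:
                fh.write(
                    f"{tag.sequence}\t{iv.chrom}\t{iv.start}\t{iv.strand}\t{mism}\n"
                )
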