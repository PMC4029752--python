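"""Cross-species conservation of antisense gene pairs.

A species-1 pair (g, h) is conserved when some species-2 pair (g', h')
exists with g' homologous to g and h' homologous to h (member order
normalized, so matches in either orientation count).  Homology is taken
from a gene-to-gene table; many-to-many relationships are allowed and every
qualifying combination is emitted, which matters for species with
triplicated genomes where one pair may have several homologous copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .pairs import CisNatPair

__all__ = [
    "HomologTable",
    "ConservationRecord",
    "read_homolog_table",
    "find_conserved_pairs",
    "conservation_summary",
    "write_records_tsv",
]


class HomologTable:
    """Mapping from species-1 gene ids to sets of species-2 gene ids."""

    def __init__(self, links: Iterable[tuple[str, str]] = ()):
        self._fwd: dict[str, set[str]] = {}
        for a, b in links:
            self.add(a, b)

    def add(self, gene1: str, gene2: str) -> None:
        self._fwd.setdefault(gene1, set()).add(gene2)

    def homologs(self, gene1: str) -> frozenset[str]:
        """Species-2 homologs of *gene1* (empty when absent from the table)."""
        return frozenset(self._fwd.get(gene1, ()))

    def inverted(self) -> "HomologTable":
        inv = HomologTable()
        for a, bs in self._fwd.items():
            for b in bs:
                inv.add(b, a)
        return inv

    def __len__(self) -> int:
        return sum(len(v) for v in self._fwd.values())


def read_homolog_table(path: str | Path) -> HomologTable:
    """Two-column TSV: species-1 gene id, species-2 gene id."""
    table = HomologTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            table.add(fields[0], fields[1])
    return table


@dataclass(frozen=True)
class ConservationRecord:
    pair_1: CisNatPair
    pair_2: CisNatPair
    copy_count: int  # species-1 pairs matched to this species-2 pair


def find_conserved_pairs(
    pairs_1: Sequence[CisNatPair],
    pairs_2: Sequence[CisNatPair],
    homologs: HomologTable,
) -> list[ConservationRecord]:
    """All (species-1 pair, species-2 pair) homologous combinations.

    Genes absent from the table simply have no homologs.  ``copy_count`` on
    each record is the number of distinct species-1 pairs matched to the
    record's species-2 pair.
    """
    by_id_2 = {}
    index_2: dict[frozenset[str], list[CisNatPair]] = {}
    for p2 in pairs_2:
        key = frozenset((p2.gene_a, p2.gene_b))
        if p2.id not in by_id_2:
            by_id_2[p2.id] = p2
            index_2.setdefault(key, []).append(p2)

    matches: list[tuple[CisNatPair, CisNatPair]] = []
    seen: set[tuple[str, str]] = set()
    for p1 in pairs_1:
        ha = homologs.homologs(p1.gene_a)
        hb = homologs.homologs(p1.gene_b)
        if not ha or not hb:
            continue
        for a2 in ha:
            for b2 in hb:
                if a2 == b2:
                    continue
                for p2 in index_2.get(frozenset((a2, b2)), ()):
                    key = (p1.id, p2.id)
                    if key not in seen:
                        seen.add(key)
                        matches.append((p1, p2))

    copies = Counter(p2.id for _, p2 in matches)
    records = [
        ConservationRecord(p1, p2, copies[p2.id]) for p1, p2 in matches
    ]
    records.sort(key=lambda r: (r.pair_1.id, r.pair_2.id))
    return records


def conservation_summary(
    records: Sequence[ConservationRecord],
    pairs_1: Sequence[CisNatPair],
    producing_subset: Iterable[str] = (),
) -> dict[str, int]:
    """Counts over distinct pair identities.

    ``producing_subset`` is the set of species-1 pair ids that generate
    small RNAs; ``conserved_and_producing`` counts its intersection with the
    conserved pairs.
    """
    ids_1 = {p.id for p in pairs_1}
    conserved_1 = {r.pair_1.id for r in records}
    if not conserved_1 <= ids_1:
        raise ValueError("records reference pairs outside pairs_1")
    producing = set(producing_subset)
    return {
        "pairs_1": len(ids_1),
        "conserved_1": len(conserved_1),
        "distinct_2": len({r.pair_2.id for r in records}),
        "specific_1": len(ids_1) - len(conserved_1),
        "conserved_and_producing": len(conserved_1 & producing),
    }


def write_records_tsv(
    records: Sequence[ConservationRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("pair_1\tpair_2\tcopy_count\n")
        for r in records:
            fh.write(f"{r.pair_1.id}\t{r.pair_2.id}\t{r.copy_count}\n")
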