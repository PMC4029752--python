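"""Summary tables over pair sets.

Builds the per-variety / shared / specific / union summary: orientation
counts, totals, how many pairs produce small RNAs (with a percentage), and
how many show strand bias.  Percentages are rounded half-up to two decimals
and rendered as ``"N (P%)"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .pairs import CisNatPair, pair_set_union

__all__ = ["SummaryRow", "build_summary", "format_percentage", "write_summary_tsv"]

ORIENTATIONS = ("convergent", "divergent", "enclosed")


def format_percentage(producing: int, total: int) -> str:
    """``"N (P%)"`` with P = producing/total*100 rounded half-up, 2 decimals."""
    if total == 0:
        pct = Decimal(0)
    else:
        pct = (
            Decimal(producing) * 100 / Decimal(total)
        ).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{producing} ({pct:.2f}%)"


@dataclass(frozen=True)
class SummaryRow:
    label: str
    convergent: int
    divergent: int
    enclosed: int
    total: int
    producing: int
    producing_pct: str
    strand_biased: int


def _row(
    label: str,
    pairs: Sequence[CisNatPair],
    producing: set[str],
    biased: set[str],
) -> SummaryRow:
    counts = {o: 0 for o in ORIENTATIONS}
    ids = set()
    for p in pairs:
        if p.id in ids:
            continue
        ids.add(p.id)
        counts[p.orientation] += 1
    n_prod = len(ids & producing)
    return SummaryRow(
        label,
        counts["convergent"],
        counts["divergent"],
        counts["enclosed"],
        len(ids),
        n_prod,
        format_percentage(n_prod, len(ids)),
        len(ids & biased),
    )


def build_summary(
    pair_sets: Mapping[str, Sequence[CisNatPair]],
    producing: Iterable[str] = (),
    biased: Iterable[str] = (),
) -> list[SummaryRow]:
    """Summary rows: one per input set, then shared, per-set specific, union.

    ``producing`` and ``biased`` are sets of pair ids (small-RNA producing
    pairs and strand-biased pairs).  Shared/specific/union rows come from
    set algebra on pair identities and satisfy inclusion-exclusion.
    """
    producing = set(producing)
    biased = set(biased)
    union = pair_set_union(pair_sets)
    rows = []
    names = list(pair_sets)
    for name in names:
        rows.append(_row(name, list(pair_sets[name]), producing, biased))
    if len(names) > 1:
        shared = [p for p in union if p.sets == frozenset(names)]
        rows.append(_row("shared", shared, producing, biased))
        for name in names:
            specific = [p for p in union if p.sets == frozenset({name})]
            rows.append(_row(f"specific:{name}", specific, producing, biased))
    rows.append(_row("union", union, producing, biased))
    return rows


def write_summary_tsv(rows: Sequence[SummaryRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "set\tconvergent\tdivergent\tenclosed\ttotal\t"
            "producing\tstrand_biased\n"
        )
        for r in rows:
            fh.write(
                f"{r.label}\t{r.convergent}\t{r.divergent}\t{r.enclosed}\t"
                f"{r.total}\t{r.producing_pct}\t{r.strand_biased}\n"
            )
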