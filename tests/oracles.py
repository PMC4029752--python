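"""Independent exact-arithmetic oracles used by the test suite.

The count-contrast probability p(y|x) = r^y * C(x+y, y) / (1+r)^(x+y+1)
with r = N2/N1 is a ratio of integers whenever r is rational, so it can be
evaluated exactly with ``fractions.Fraction`` — no floating point, no shared
code with the implementation under test.
"""

from fractions import Fraction
from math import comb


def exact_point_prob(x: int, y: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def exact_lower_tail(x: int, y: int, n1: int, n2: int) -> Fraction:
    return sum(exact_point_prob(x, k, n1, n2) for k in range(y + 1))


def exact_upper_tail(x: int, y: int, n1: int, n2: int) -> Fraction:
    return 1 - sum(exact_point_prob(x, k, n1, n2) for k in range(y))


def exact_two_sided(x: int, y: int, n1: int, n2: int) -> Fraction:
    lo = exact_lower_tail(x, y, n1, n2)
    up = exact_upper_tail(x, y, n1, n2)
    return min(Fraction(1), 2 * min(lo, up))


def brute_force_pairs(models, min_overlap, max_overlap):
    """O(n^2) antisense-pair finder over (gene_id, chrom, start, end, strand)
    tuples; orientation decided by direct case analysis on the endpoints."""
    out = set()
    for ga, ca, a1, a2, sa in models:
        for gb, cb, b1, b2, sb in models:
            if sa != "+" or sb != "-" or ca != cb:
                continue
            ov = min(a2, b2) - max(a1, b1)
            if not (min_overlap <= ov <= max_overlap):
                continue
            if (a1 <= b1 and b2 <= a2) or (b1 <= a1 and a2 <= b2):
                orient = "enclosed"
            elif a1 < b1:
                orient = "convergent"
            else:
                orient = "divergent"
            out.add((tuple(sorted((ga, gb))), orient))
    return out
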