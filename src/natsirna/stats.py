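"""Count-contrast significance testing for tag abundances.

The core statistic compares a tag's raw counts ``x`` and ``y`` in two
sequencing libraries of total sizes ``N1`` and ``N2`` (Audic–Claverie):

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

which is the probability of observing ``y`` in library 2 given ``x`` in
library 1 under a common per-nucleotide Poisson rate.  Writing
r = N2/N1, this is exactly the negative-binomial pmf with x+1 "successes"
and success probability 1/(1+r):

    p(y | x) = C(x+y, y) * (r/(1+r))^y * (1/(1+r))^(x+1)

so cumulative tails are regularized incomplete beta functions, which is how
they are evaluated here (numerically stable for large counts).  The
significance reported by default is the two-sided tail: twice the smaller of
the lower and upper tails, capped at 1, with the observed point mass counted
in both tails (conservative for a discrete statistic).

Two decision procedures are built on the test:

* strand bias — forward-strand vs reverse-strand read totals (FR vs RR) of
  one library, called biased when FR/RR lies outside [0.5, 2] and p < 0.01;
  both strands come from the same library, so N1 = N2.
* heat response — per-replicate high-temperature vs normal-temperature
  totals; called when both replicates change > 2-fold in the same direction
  with p < 0.01 (raw p values; the original procedure applies no
  multiple-testing correction, and neither do we).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.special import gammaln
from scipy.stats import nbinom

__all__ = [
    "CountContrast",
    "StrandBiasCall",
    "HeatResponseCall",
    "ac_point_probability",
    "ac_p_value",
    "ac_p_value_array",
    "rp10m",
    "call_strand_bias",
    "call_heat_response",
    "ratio_with_conventions",
    "format_ratio",
]


@dataclass(frozen=True)
class CountContrast:
    """Raw counts x, y and library totals N1, N2 for the pairwise test."""

    x: int
    y: int
    N1: float
    N2: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("library totals must be positive")


def ac_point_probability(c: CountContrast) -> float:
    """Point probability p(y|x), evaluated in log space."""
    r = c.N2 / c.N1
    log_p = (
        c.y * math.log(r)
        + gammaln(c.x + c.y + 1)
        - gammaln(c.x + 1)
        - gammaln(c.y + 1)
        - (c.x + c.y + 1) * math.log1p(r)
    )
    return math.exp(log_p)


def ac_p_value(c: CountContrast, sided: str = "two") -> float:
    """Tail probability of the count contrast.

    ``lower`` sums p(k|x) for k <= y; ``upper`` is 1 minus the sum for
    k < y (so the point mass belongs to both tails); ``two`` doubles the
    smaller tail, capped at 1.
    """
    r = c.N2 / c.N1
    q = 1.0 / (1.0 + r)  # nbinom success probability
    lower = float(nbinom.cdf(c.y, c.x + 1, q))
    upper = float(nbinom.sf(c.y - 1, c.x + 1, q)) if c.y > 0 else 1.0
    if sided == "lower":
        return min(1.0, lower)
    if sided == "upper":
        return min(1.0, upper)
    if sided == "two":
        return min(1.0, 2.0 * min(lower, upper))
    raise ValueError(f"sided must be lower/upper/two, got {sided!r}")


def ac_p_value_array(
    x: np.ndarray, y: np.ndarray, N1: float, N2: float
) -> np.ndarray:
    """Vectorized two-sided p-values for many contrasts (shared totals)."""
    x = np.asarray(x)
    y = np.asarray(y)
    q = 1.0 / (1.0 + N2 / N1)
    lower = nbinom.cdf(y, x + 1, q)
    upper = np.where(y > 0, nbinom.sf(y - 1, x + 1, q), 1.0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def ratio_with_conventions(num: float, den: float) -> Optional[float]:
    """num/den with the reporting conventions used for count ratios.

    Returns ``inf`` when den == 0 and num > 0, ``0.0`` when num == 0 and
    den > 0, and ``None`` (undefined) when both are zero.
    """
    if num == 0 and den == 0:
        return None
    if den == 0:
        return math.inf
    return num / den


def format_ratio(ratio: Optional[float], decimals: int = 2) -> str:
    """Serialize a ratio; infinity prints as the literal ``INF``."""
    if ratio is None:
        return "NA"
    if math.isinf(ratio):
        return "INF"
    return f"{ratio:.{decimals}f}"


@dataclass(frozen=True)
class StrandBiasCall:
    pair_id: str
    FR: int
    RR: int
    ratio: Optional[float]
    p_value: float
    biased: bool


def call_strand_bias(
    FR: int,
    RR: int,
    pair_id: str = "",
    ratio_hi: float = 2.0,
    ratio_lo: float = 0.5,
    alpha: float = 0.01,
) -> StrandBiasCall:
    """Call strand-biased small-RNA production from forward/reverse totals.

    FR and RR come from the same library, so the test runs with N1 = N2.
    The test conditions on the larger of the two totals: which strand plays
    the role of the observed count is arbitrary here, and conditioning on the
    larger one makes the call symmetric under swapping FR and RR.  Biased
    requires the ratio outside [ratio_lo, ratio_hi] (INF and 0 count as
    outside) and a two-sided p below alpha.  Both-zero input is never biased
    and has an undefined ratio.
    """
    if FR < 0 or RR < 0:
        raise ValueError("strand totals must be non-negative")
    ratio = ratio_with_conventions(FR, RR)
    if ratio is None:
        return StrandBiasCall(pair_id, FR, RR, None, 1.0, False)
    x, y = max(FR, RR), min(FR, RR)
    p = ac_p_value(CountContrast(x, y, 1.0, 1.0), sided="two")
    extreme = ratio > ratio_hi or ratio < ratio_lo
    return StrandBiasCall(pair_id, FR, RR, ratio, p, extreme and p < alpha)


@dataclass(frozen=True)
class HeatResponseCall:
    pair_id: str
    ratio_rep1: Optional[float]
    ratio_rep2: Optional[float]
    p_rep1: float
    p_rep2: float
    direction: str  # up | down | none
    significant: bool


def call_heat_response(
    totals: Mapping[str, int],
    library_totals: Mapping[str, float],
    pair_id: str = "",
    fold: float = 2.0,
    alpha: float = 0.01,
) -> HeatResponseCall:
    """Replicate-concordant differential-accumulation call.

    ``totals`` holds per-pair raw nat-siRNA read totals keyed NT1, HT1, NT2,
    HT2; ``library_totals`` the total mapped reads of the same four
    libraries.  Per replicate k the ratio is the RP10M-normalized HT_k/NT_k
    (with the INF/0 conventions) and the p-value the two-sided count test on
    raw counts with true library sizes.  Direction is ``up`` iff both ratios
    exceed ``fold``, ``down`` iff both fall below ``1/fold``; the call is
    significant iff the direction is concordant and both p < alpha.
    """
    required = ("NT1", "HT1", "NT2", "HT2")
    for key in required:
        if key not in totals or key not in library_totals:
            raise ValueError(f"missing replicate data for {key}")

    ratios = []
    pvals = []
    for k in ("1", "2"):
        nt, ht = totals[f"NT{k}"], totals[f"HT{k}"]
        n_nt, n_ht = library_totals[f"NT{k}"], library_totals[f"HT{k}"]
        ratios.append(
            ratio_with_conventions(rp10m(ht, n_ht), rp10m(nt, n_nt))
        )
        pvals.append(
            ac_p_value(CountContrast(nt, ht, n_nt, n_ht), sided="two")
        )

    def _both(pred) -> bool:
        return all(r is not None and pred(r) for r in ratios)

    if _both(lambda r: r > fold):
        direction = "up"
    elif _both(lambda r: r < 1.0 / fold):
        direction = "down"
    else:
        direction = "none"
    significant = direction != "none" and all(p < alpha for p in pvals)
    return HeatResponseCall(
        pair_id, ratios[0], ratios[1], pvals[0], pvals[1], direction, significant
    )


def rp10m(count: float, total: float) -> float:
    """Reads per 10 million: count * 1e7 / total."""
    if total <= 0:
        raise ValueError("library total must be positive")
    return count * 1e7 / total
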