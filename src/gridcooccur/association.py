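"""Pairwise association tests for a species pair from its 2x2 table.

Seven tests are provided:

* a Chi-squared test of independence (1 d.f.) with a continuity-corrected
  variant triggered whenever any expected count falls below ten;
* six directional tail tests, ``P1``–``P6``, built from the counts
  ``O1..O4``, which under the randomness null are marginally binomial,
  ``Oi ~ Bin(N, Ei/N)``, and approximately Poisson with mean ``Ei`` when
  ``N`` is large and ``Ei/N`` small;
* the hypergeometric benchmark ``P7``: the exact distribution of the
  co-occurrence count ``O1`` when both marginal presence totals are held
  fixed (Veech's probabilistic method).

All tails are inclusive of the observed value, i.e. ``P(O >= o)`` for the
positive direction and ``P(O <= o)`` for the negative direction, so for any
one count statistic ``p_pos + p_neg = 1 + P(O = o)``.

``P2`` and ``P3`` multiply the two marginal tails as if the components were
independent; this deliberate approximation (the components are negatively
correlated multinomial counts) is what gives ``P2`` its power advantage at
extreme presence rates, and the exact joint version is intentionally not
substituted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .contingency import ContingencyTable, ExpectedCounts, expected_counts, tabulate
from .gridmap import PresenceAbsenceMap

__all__ = [
    "Direction",
    "ChiSquaredResult",
    "TestReport",
    "DegenerateTableError",
    "METHODS",
    "chi_squared",
    "p1_binomial",
    "p2_binomial_pair",
    "p3_binomial_pair",
    "p4_poisson",
    "p5_poisson_sum",
    "p6_poisson_sum",
    "p7_hypergeometric",
    "p_value",
    "run_all",
]

#: Identifiers of the seven directional tests, in reporting order.
METHODS = ("P1", "P2", "P3", "P4", "P5", "P6", "P7")

#: Expected-count threshold below which the continuity correction is applied.
YATES_THRESHOLD = 10.0


class Direction(enum.Enum):
    """Alternative hypothesis being tested: positive or negative association."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


class DegenerateTableError(ValueError):
    """Raised when an expected count is zero and a test is undefined."""


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    p_value: float
    yates_applied: bool
    df: int = 1


@dataclass(frozen=True)
class TestReport:
    """All test results for one species pair."""

    table: ContingencyTable
    expected: ExpectedCounts
    chi: ChiSquaredResult | None
    p: Mapping[tuple[str, Direction], float]
    degenerate: bool


def chi_squared(table: ContingencyTable) -> ChiSquaredResult:
    """Chi-squared test of independence on the 2x2 table.

    The plain statistic ``sum((oi - Ei)^2 / Ei)`` is used when every
    expected count is at least ten; otherwise each ``|oi - Ei|`` is reduced
    by 0.5 before squaring (clamped at zero when 0.5 exceeds the
    deviation).  The p-value is the upper tail of the 1-d.f. Chi-squared
    distribution.
    """
    exp = expected_counts(table)
    e = exp.as_array()
    if np.any(e == 0):
        raise DegenerateTableError(
            f"chi-squared undefined: zero expected count for table "
            f"(o1..o4)=({table.o1},{table.o2},{table.o3},{table.o4})"
        )
    o = np.array([table.o1, table.o2, table.o3, table.o4], dtype=float)
    yates = bool(np.min(e) < YATES_THRESHOLD)
    if yates:
        dev = np.maximum(np.abs(o - e) - 0.5, 0.0)
    else:
        dev = o - e
    stat = float(np.sum(dev**2 / e))
    return ChiSquaredResult(stat, float(stats.chi2.sf(stat, df=1)), yates)


def _binom_tail(o: int, n: int, p: float, direction: Direction) -> float:
    """Inclusive binomial tail: P(O >= o) or P(O <= o) for O ~ Bin(n, p)."""
    if direction is Direction.POSITIVE:
        return float(stats.binom.sf(o - 1, n, p))
    return float(stats.binom.cdf(o, n, p))


def _poisson_tail(o: int, mean: float, direction: Direction) -> float:
    """Inclusive Poisson tail: P(O >= o) or P(O <= o) for O ~ Poi(mean)."""
    if direction is Direction.POSITIVE:
        return float(stats.poisson.sf(o - 1, mean))
    return float(stats.poisson.cdf(o, mean))


def _flip(direction: Direction) -> Direction:
    return Direction.NEGATIVE if direction is Direction.POSITIVE else Direction.POSITIVE


def p1_binomial(table: ContingencyTable, direction: Direction) -> float:
    """Tail of the co-occurrence count O1 under Bin(N, E1/N)."""
    e = expected_counts(table)
    n = table.n_cells
    return _binom_tail(table.o1, n, e.e1 / n, direction)


def p2_binomial_pair(table: ContingencyTable, direction: Direction) -> float:
    """Product of the O1 and O2 binomial tails (both upper for positive
    association, both lower for negative)."""
    e = expected_counts(table)
    n = table.n_cells
    return _binom_tail(table.o1, n, e.e1 / n, direction) * _binom_tail(
        table.o2, n, e.e2 / n, direction
    )


def p3_binomial_pair(table: ContingencyTable, direction: Direction) -> float:
    """Product of the O3 and O4 binomial tails (both lower for positive
    association — exclusive counts should be small — and upper for negative)."""
    e = expected_counts(table)
    n = table.n_cells
    flipped = _flip(direction)
    return _binom_tail(table.o3, n, e.e3 / n, flipped) * _binom_tail(
        table.o4, n, e.e4 / n, flipped
    )


def p4_poisson(table: ContingencyTable, direction: Direction) -> float:
    """Tail of O1 under the Poisson approximation Poi(E1)."""
    e = expected_counts(table)
    return _poisson_tail(table.o1, e.e1, direction)


def p5_poisson_sum(table: ContingencyTable, direction: Direction) -> float:
    """Tail of O1 + O2 under Poi(E1 + E2)."""
    e = expected_counts(table)
    return _poisson_tail(table.o1 + table.o2, e.e1 + e.e2, direction)


def p6_poisson_sum(table: ContingencyTable, direction: Direction) -> float:
    """Tail of O3 + O4 under Poi(E3 + E4), lower tail for positive
    association."""
    e = expected_counts(table)
    return _poisson_tail(table.o3 + table.o4, e.e3 + e.e4, _flip(direction))


def _log_hypergeom_pmf(j: np.ndarray, n: int, n_a: int, n_b: int) -> np.ndarray:
    """Log-probability that exactly j cells hold both species when Na and Nb
    occupied cells are placed uniformly at random among n cells.

    Computed from the combinatorial form C(n,j) C(n-j, Nb-j) C(n-Nb, Na-j)
    / (C(n,Nb) C(n,Na)) in log-gamma arithmetic, which is stable for the
    tens of thousands of cells arising from fine grids.
    """

    def logc(top, bottom):
        top = np.asarray(top, dtype=float)
        bottom = np.asarray(bottom, dtype=float)
        return gammaln(top + 1) - gammaln(bottom + 1) - gammaln(top - bottom + 1)

    return (
        logc(n, j)
        + logc(n - j, n_b - j)
        + logc(n - n_b, n_a - j)
        - logc(n, n_b)
        - logc(n, n_a)
    )


def p7_hypergeometric(table: ContingencyTable, direction: Direction) -> float:
    """Exact tail of O1 with both presence totals fixed (Veech's method).

    The support is ``max(0, Na+Nb-N) <= j <= min(Na, Nb)``; the positive
    direction sums masses for ``j >= o1``, the negative for ``j <= o1``.
    """
    n, n_a, n_b, o1 = table.n_cells, table.n_a, table.n_b, table.o1
    j_lo = max(0, n_a + n_b - n)
    j_hi = min(n_a, n_b)
    if not j_lo <= o1 <= j_hi:
        raise ValueError(
            f"observed co-occurrence {o1} outside support [{j_lo}, {j_hi}] "
            f"for N={n}, Na={n_a}, Nb={n_b}: inconsistent table"
        )
    if direction is Direction.POSITIVE:
        j = np.arange(o1, j_hi + 1)
    else:
        j = np.arange(j_lo, o1 + 1)
    return float(min(1.0, np.exp(logsumexp(_log_hypergeom_pmf(j, n, n_a, n_b)))))


_P_FUNCS = {
    "P1": p1_binomial,
    "P2": p2_binomial_pair,
    "P3": p3_binomial_pair,
    "P4": p4_poisson,
    "P5": p5_poisson_sum,
    "P6": p6_poisson_sum,
    "P7": p7_hypergeometric,
}


def p_value(method: str, table: ContingencyTable, direction: Direction) -> float:
    """Dispatch a single directional test by its identifier (P1..P7)."""
    try:
        func = _P_FUNCS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}") from None
    return func(table, direction)


def run_all(
    map_a: PresenceAbsenceMap,
    map_b: PresenceAbsenceMap,
) -> TestReport:
    """Tabulate a species pair and run every test in both directions.

    Degenerate marginals (a species present everywhere or nowhere) make the
    Chi-squared test undefined; the tail tests remain well defined (a point
    mass at zero gives trivially correct tails) and the report is flagged.
    """
    table = tabulate(map_a, map_b)
    exp = expected_counts(table)
    degenerate = table.degenerate
    chi: ChiSquaredResult | None
    if degenerate:
        warnings.warn(
            f"degenerate marginals (Na={table.n_a}, Nb={table.n_b}, N={table.n_cells}): "
            "chi-squared skipped, tail tests may be uninformative",
            stacklevel=2,
        )
        chi = None
    else:
        chi = chi_squared(table)
    p = {
        (m, d): p_value(m, table, d)
        for m in METHODS
        for d in (Direction.POSITIVE, Direction.NEGATIVE)
    }
    return TestReport(table=table, expected=exp, chi=chi, p=p, degenerate=degenerate)
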