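"""Directional tail tests and the chi-squared independence test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridcooccur import (
    ContingencyTable,
    DegenerateTableError,
    Direction,
    GridSpec,
    METHODS,
    PresenceAbsenceMap,
    Window,
    chi_squared,
    expected_counts,
    p1_binomial,
    p2_binomial_pair,
    p3_binomial_pair,
    p4_poisson,
    p5_poisson_sum,
    p6_poisson_sum,
    p7_hypergeometric,
    p_value,
    run_all,
)

POS, NEG = Direction.POSITIVE, Direction.NEGATIVE

# Small tables used repeatedly below: all margins of the N=4 examples give
# unit expected counts E1..E4 = 1.
T2200 = ContingencyTable(2, 2, 0, 0)
T0022 = ContingencyTable(0, 0, 2, 2)
T1111 = ContingencyTable(1, 1, 1, 1)

tables = st.tuples(*[st.integers(0, 40)] * 4).filter(lambda o: sum(o) >= 2).map(
    lambda o: ContingencyTable(*o)
)
nondegenerate_tables = tables.filter(lambda t: not t.degenerate)


class TestChiSquared:
    def test_plain_statistic_hand_value(self):
        res = chi_squared(ContingencyTable(40, 40, 10, 10))
        assert res.statistic == pytest.approx(36.0)
        assert not res.yates_applied

    def test_yates_statistic_hand_value(self):
        res = chi_squared(T2200)
        assert res.statistic == pytest.approx(1.0)
        assert res.yates_applied

    def test_perfect_fit_gives_zero_statistic(self):
        res = chi_squared(ContingencyTable(100, 100, 100, 100))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_expected_count_errors(self):
        with pytest.raises(DegenerateTableError):
            chi_squared(ContingencyTable(0, 10, 0, 10))

    @given(nondegenerate_tables)
    @settings(max_examples=100, deadline=None)
    def test_yates_never_exceeds_plain_statistic(self, t):
        e = expected_counts(t).as_array()
        o = np.array([t.o1, t.o2, t.o3, t.o4], dtype=float)
        plain = float(np.sum((o - e) ** 2 / e))
        assert chi_squared(t).statistic <= plain + 1e-12


class TestFrozenExamples:
    """Hand-evaluated tail probabilities on the unit-expectation tables."""

    @pytest.mark.parametrize(
        "func, table, direction, expected",
        [
            (p1_binomial, T2200, POS, 1 - 0.75**4 - 4 * 0.25 * 0.75**3),
            (p1_binomial, T0022, NEG, 0.75**4),
            (p2_binomial_pair, T2200, POS, (1 - 0.75**4 - 4 * 0.25 * 0.75**3) ** 2),
            (p3_binomial_pair, T2200, POS, (0.75**4) ** 2),
            (p4_poisson, T2200, POS, 1 - 2 * math.exp(-1)),
            (p4_poisson, T0022, NEG, math.exp(-1)),
            (p5_poisson_sum, T1111, POS, 1 - 3 * math.exp(-2)),
            (p5_poisson_sum, T0022, NEG, math.exp(-2)),
            (p6_poisson_sum, T2200, POS, math.exp(-2)),
            (p7_hypergeometric, T2200, POS, 1 / 6),
            (p7_hypergeometric, T0022, POS, 1.0),  # o1 at the support minimum
        ],
    )
    def test_tail_value(self, func, table, direction, expected):
        assert func(table, direction) == pytest.approx(expected, abs=1e-12)

    def test_zero_observation_upper_tails_are_one(self):
        t = ContingencyTable(0, 0, 3, 3)
        assert p1_binomial(t, POS) == pytest.approx(1.0)
        assert p2_binomial_pair(t, POS) == pytest.approx(1.0)
        assert p5_poisson_sum(t, POS) == pytest.approx(1.0)


def _pmf(method: str, table: ContingencyTable) -> float:
    """Null point mass at the observed value of the method's count statistic."""
    from scipy import stats

    e = expected_counts(table)
    n = table.n_cells
    if method == "P1":
        return stats.binom.pmf(table.o1, n, e.e1 / n)
    if method == "P4":
        return stats.poisson.pmf(table.o1, e.e1)
    if method == "P5":
        return stats.poisson.pmf(table.o1 + table.o2, e.e1 + e.e2)
    if method == "P6":
        return stats.poisson.pmf(table.o3 + table.o4, e.e3 + e.e4)
    if method == "P7":
        return stats.hypergeom.pmf(table.o1, n, table.n_b, table.n_a)
    raise AssertionError(method)


class TestTailProperties:
    @given(tables)
    @settings(max_examples=100, deadline=None)
    def test_all_p_values_in_unit_interval(self, t):
        for m in METHODS:
            for d in (POS, NEG):
                assert 0.0 <= p_value(m, t, d) <= 1.0

    @pytest.mark.parametrize("method", ["P1", "P4", "P5", "P6", "P7"])
    @given(t=tables)
    @settings(max_examples=60, deadline=None)
    def test_inclusive_tails_overlap_by_point_mass(self, method, t):
        # P(O >= o) + P(O <= o) = 1 + P(O = o) for a single count statistic
        gap = p_value(method, t, POS) + p_value(method, t, NEG) - 1.0
        assert gap == pytest.approx(_pmf(method, t), abs=1e-9)

    @given(tables)
    @settings(max_examples=60, deadline=None)
    def test_p2_no_larger_than_p1(self, t):
        assert p2_binomial_pair(t, POS) <= p1_binomial(t, POS) + 1e-12
        assert p2_binomial_pair(t, NEG) <= p1_binomial(t, NEG) + 1e-12

    @given(tables)
    @settings(max_examples=60, deadline=None)
    def test_label_swap_leaves_every_p_value_unchanged(self, t):
        s = t.swapped()
        for m in METHODS:
            for d in (POS, NEG):
                assert p_value(m, t, d) == pytest.approx(p_value(m, s, d), abs=1e-12)

    @pytest.mark.parametrize("method", ["P1", "P4", "P7"])
    def test_positive_tail_non_increasing_in_cooccurrence(self, method):
        # hold N and both margins (hence E1) fixed while o1 grows
        n, n_a, n_b = 100, 40, 30
        values = [
            p_value(
                method,
                ContingencyTable(o1, n - n_a - n_b + o1, n_a - o1, n_b - o1),
                POS,
            )
            for o1 in range(0, n_b + 1)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_poisson_approaches_binomial_for_large_sparse_grids(self):
        # same statistic O1 under Bin(N, E1/N) vs Poi(E1): N=10^4, E1=5
        n, n_a, n_b = 10_000, 250, 200
        for o1 in range(0, 16):
            t = ContingencyTable(o1, n - n_a - n_b + o1, n_a - o1, n_b - o1)
            assert abs(p4_poisson(t, POS) - p1_binomial(t, POS)) < 0.01
            assert abs(p4_poisson(t, NEG) - p1_binomial(t, NEG)) < 0.01


class TestRunAll:
    def test_identical_maps_scream_positive(self, grid20):
        rng = np.random.default_rng(3)
        occ = rng.random((20, 20)) < 0.4
        m = PresenceAbsenceMap(grid20, occ, "A")
        report = run_all(m, PresenceAbsenceMap(grid20, occ, "B"))
        for method in METHODS:
            assert report.p[(method, POS)] < 1e-6
            assert report.p[(method, NEG)] > 0.999
        assert report.chi is not None and report.chi.p_value < 1e-6

    def test_complementary_maps_scream_negative(self, grid20):
        rng = np.random.default_rng(4)
        occ = rng.random((20, 20)) < 0.5
        a = PresenceAbsenceMap(grid20, occ, "A")
        b = PresenceAbsenceMap(grid20, ~occ, "B")
        report = run_all(a, b)
        assert report.p[("P1", NEG)] < 1e-6
        assert report.p[("P7", NEG)] < 1e-6

    def test_degenerate_marginals_flagged_not_fatal(self, grid20):
        empty = PresenceAbsenceMap(grid20, np.zeros((20, 20), dtype=bool), "gone")
        rng = np.random.default_rng(5)
        other = PresenceAbsenceMap(grid20, rng.random((20, 20)) < 0.5, "B")
        with pytest.warns(UserWarning, match="degenerate"):
            report = run_all(empty, other)
        assert report.degenerate
        assert report.chi is None
        # the co-occurrence count can only be zero, so its upper tail is 1
        assert report.p[("P1", POS)] == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in report.p.values())

    def test_report_has_fourteen_p_values(self, random_map_pair):
        report = run_all(*random_map_pair)
        assert len(report.p) == 14
        assert set(report.p) == {(m, d) for m in METHODS for d in (POS, NEG)}
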