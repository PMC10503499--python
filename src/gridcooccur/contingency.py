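"""2x2 presence/absence contingency tables and their expected counts.

For a species pair (A, B) on a grid of ``N`` cells, the table counts cells
with both species present (``o1``), neither present (``o2``), only A
(``o3``) and only B (``o4``).  Under the null hypothesis that every
individual lands in any cell with equal probability, independently of the
other species, the expected counts are products of the marginal presence
totals: ``E1 = Na*Nb/N`` and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridmap import PresenceAbsenceMap

__all__ = ["ContingencyTable", "ExpectedCounts", "tabulate", "expected_counts"]


@dataclass(frozen=True)
class ContingencyTable:
    """Observed 2x2 cell counts: both, neither, A only, B only."""

    o1: int
    o2: int
    o3: int
    o4: int

    def __post_init__(self) -> None:
        for name in ("o1", "o2", "o3", "o4"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def n_cells(self) -> int:
        return self.o1 + self.o2 + self.o3 + self.o4

    @property
    def n_a(self) -> int:
        """Cells where species A is present."""
        return self.o1 + self.o3

    @property
    def n_b(self) -> int:
        """Cells where species B is present."""
        return self.o1 + self.o4

    @property
    def degenerate(self) -> bool:
        """True when either species is present everywhere or nowhere, which
        collapses at least one null distribution to a point mass at zero."""
        n = self.n_cells
        return self.n_a in (0, n) or self.n_b in (0, n)

    def swapped(self) -> "ContingencyTable":
        """The same pair with species labels exchanged (o3 and o4 swap)."""
        return ContingencyTable(self.o1, self.o2, self.o4, self.o3)


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected 2x2 cell counts under the randomness null."""

    e1: float
    e2: float
    e3: float
    e4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.e1, self.e2, self.e3, self.e4])


def tabulate(map_a: PresenceAbsenceMap, map_b: PresenceAbsenceMap) -> ContingencyTable:
    """Cross-tabulate two presence-absence maps on the same grid."""
    if map_a.occupancy.shape != map_b.occupancy.shape:
        raise ValueError(
            f"grid shapes differ: {map_a.occupancy.shape} vs {map_b.occupancy.shape}"
        )
    if map_a.grid.window != map_b.grid.window:
        raise ValueError(
            f"windows differ: {map_a.grid.window} vs {map_b.grid.window}"
        )
    a = map_a.occupancy
    b = map_b.occupancy
    return ContingencyTable(
        o1=int(np.sum(a & b)),
        o2=int(np.sum(~a & ~b)),
        o3=int(np.sum(a & ~b)),
        o4=int(np.sum(~a & b)),
    )


def expected_counts(table: ContingencyTable) -> ExpectedCounts:
    """Expected cell counts E1..E4 under independent random placement.

    E1 = Na*Nb/N, E2 = (N-Na)(N-Nb)/N, E3 = Na(N-Nb)/N, E4 = (N-Na)Nb/N.
    They sum to N and satisfy E1*E2 = E3*E4.
    """
    n = table.n_cells
    if n < 1:
        raise ValueError("table must have at least one cell")
    na, nb = table.n_a, table.n_b
    return ExpectedCounts(
        e1=na * nb / n,
        e2=(n - na) * (n - nb) / n,
        e3=na * (n - nb) / n,
        e4=(n - na) * nb / n,
    )
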