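"""Monte-Carlo study runner: type-I error and power of the association tests.

Five scenarios are supported.  Scenario 1 draws two independent uniform
patterns of fixed abundance (the null of random association); scenarios
2–5 draw independent inhomogeneous Poisson patterns whose shared or
opposed linear gradients induce positive or negative association:

* Scenario 2 — both species share the intensity ``c*x`` (positive, similar
  presences);
* Scenario 3 — species A fixed at ``400x``, species B swept over ``c*x``
  (positive, dissimilar presences);
* Scenario 4 — species A at ``c*(1-x)`` against species B at ``c*x``
  (negative, similar presences);
* Scenario 5 — species A fixed at ``400(1-x)``, species B swept over
  ``c*x`` (negative, dissimilar presences).

Each replicate simulates both species, rasterizes them on the grid
(default 20x20 over the unit square, i.e. 400 cells of size 0.05), builds
the 2x2 table and scores every test on the same data; a test rejects when
its p-value is at most ``alpha``.  The rejection proportion over
replicates estimates the type-I error (scenario 1) or power (2–5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import (
    METHODS,
    ChiSquaredResult,
    Direction,
    chi_squared,
    p_value,
)
from .contingency import tabulate
from .gridmap import GridSpec, Window, rasterize
from .simulate import IntensityFunction, runif_points, rpoispp, split_seed

__all__ = [
    "ScenarioSpec",
    "StudyRow",
    "run_scenario",
    "run_table",
    "table_specs",
    "DEFAULT_GRID",
    "DEFAULT_REPLICATES",
]

DEFAULT_GRID = GridSpec(Window.unit_square(), nx=20, ny=20)
DEFAULT_REPLICATES = 500
DEFAULT_ALPHA = 0.05

#: Intensity coefficients swept in the power tables.
POWER_SWEEP = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 2000, 3000, 4000, 5000)

#: Abundances used under the null scenario.
NULL_ABUNDANCES = (20, 40, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of a simulation study.

    ``gen_a``/``gen_b`` are either integer abundances (scenario 1, uniform
    patterns) or :class:`IntensityFunction` objects (scenarios 2–5).
    """

    scenario: int
    gen_a: int | IntensityFunction
    gen_b: int | IntensityFunction
    grid: GridSpec = DEFAULT_GRID
    replicates: int = DEFAULT_REPLICATES
    alpha: float = DEFAULT_ALPHA
    direction: Direction = Direction.POSITIVE

    def __post_init__(self) -> None:
        if self.scenario not in range(1, 6):
            raise ValueError(f"scenario must be in 1..5, got {self.scenario}")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class StudyRow:
    """Summaries of one scenario run: mean abundances, mean presence-cell
    counts, and per-test rejection proportions in both directions."""

    spec: ScenarioSpec
    mean_abundance_a: float
    mean_abundance_b: float
    mean_presence_a: float
    mean_presence_b: float
    chi_rejection: float
    rejections: dict[tuple[str, Direction], float] = field(repr=False)

    def rejection(self, method: str, direction: Direction | None = None) -> float:
        if direction is None:
            direction = self.spec.direction
        return self.rejections[(method, direction)]


def _simulate_species(gen, grid: GridSpec, seed) -> np.ndarray:
    if isinstance(gen, IntensityFunction):
        pattern = rpoispp(gen, grid.window, seed)
    else:
        pattern = runif_points(int(gen), grid.window, seed)
    return pattern


def run_scenario(spec: ScenarioSpec, seed=None) -> StudyRow:
    """Run one scenario and return its summary row.

    All tests are scored on the same replicate data, which removes
    between-method Monte-Carlo noise from power comparisons.  Rejection
    uses ``p <= alpha``.
    """
    rep_seeds = split_seed(seed, spec.replicates)
    n_a = np.empty(spec.replicates)
    n_b = np.empty(spec.replicates)
    pres_a = np.empty(spec.replicates)
    pres_b = np.empty(spec.replicates)
    chi_reject = 0
    reject = {
        (m, d): 0 for m in METHODS for d in (Direction.POSITIVE, Direction.NEGATIVE)
    }
    for r, rep_seed in enumerate(rep_seeds):
        seed_a, seed_b = rep_seed.spawn(2)
        pat_a = _simulate_species(spec.gen_a, spec.grid, seed_a)
        pat_b = _simulate_species(spec.gen_b, spec.grid, seed_b)
        map_a = rasterize(pat_a, spec.grid)
        map_b = rasterize(pat_b, spec.grid)
        n_a[r] = pat_a.n_points
        n_b[r] = pat_b.n_points
        pres_a[r] = map_a.n_present
        pres_b[r] = map_b.n_present
        table = tabulate(map_a, map_b)
        if not table.degenerate and chi_squared(table).p_value <= spec.alpha:
            chi_reject += 1
        for m in METHODS:
            for d in (Direction.POSITIVE, Direction.NEGATIVE):
                if p_value(m, table, d) <= spec.alpha:
                    reject[(m, d)] += 1
    r_tot = spec.replicates
    return StudyRow(
        spec=spec,
        mean_abundance_a=float(n_a.mean()),
        mean_abundance_b=float(n_b.mean()),
        mean_presence_a=float(pres_a.mean()),
        mean_presence_b=float(pres_b.mean()),
        chi_rejection=chi_reject / r_tot,
        rejections={k: v / r_tot for k, v in reject.items()},
    )


def _gen_label(gen) -> str:
    return str(gen)


def run_table(specs: list[ScenarioSpec], seed=None) -> pd.DataFrame:
    """Run a list of scenario rows with split seeds and tidy the results.

    Columns: generator labels, mean abundances, mean presence cells, the
    chi-squared rejection proportion, and one column per directional test
    (``P1_pos`` .. ``P7_neg``).
    """
    rows = []
    for spec, row_seed in zip(specs, split_seed(seed, len(specs))):
        row = run_scenario(spec, row_seed)
        rec: dict[str, object] = {
            "scenario": spec.scenario,
            "gen_a": _gen_label(spec.gen_a),
            "gen_b": _gen_label(spec.gen_b),
            "mean_abundance_a": row.mean_abundance_a,
            "mean_abundance_b": row.mean_abundance_b,
            "mean_presence_a": row.mean_presence_a,
            "mean_presence_b": row.mean_presence_b,
            "chi2": row.chi_rejection,
        }
        for d, tag in ((Direction.POSITIVE, "pos"), (Direction.NEGATIVE, "neg")):
            for m in METHODS:
                rec[f"{m}_{tag}"] = row.rejections[(m, d)]
        rows.append(rec)
    columns = [
        "scenario", "gen_a", "gen_b",
        "mean_abundance_a", "mean_abundance_b",
        "mean_presence_a", "mean_presence_b", "chi2",
    ] + [f"{m}_pos" for m in METHODS] + [f"{m}_neg" for m in METHODS]
    return pd.DataFrame(rows, columns=columns)


def _lin_up(c: float) -> IntensityFunction:
    return IntensityFunction.parse(f"{c}x")


def _lin_down(c: float) -> IntensityFunction:
    return IntensityFunction.parse(f"{c}(1-x)")


def table_specs(
    table: int,
    replicates: int = DEFAULT_REPLICATES,
    grid: GridSpec = DEFAULT_GRID,
    alpha: float = DEFAULT_ALPHA,
) -> list[ScenarioSpec]:
    """Scenario rows reproducing the layout of the six study tables.

    Table 1: null, chi-squared type-I error across abundances.
    Tables 2–5: power under scenarios 2–5 across the intensity sweep.
    Table 6: null, type-I error of all directional tests across abundances.
    """
    common = dict(grid=grid, replicates=replicates, alpha=alpha)
    if table in (1, 6):
        return [
            ScenarioSpec(1, n, n, direction=Direction.POSITIVE, **common)
            for n in NULL_ABUNDANCES
        ]
    if table == 2:
        return [
            ScenarioSpec(2, _lin_up(c), _lin_up(c), direction=Direction.POSITIVE, **common)
            for c in POWER_SWEEP
        ]
    if table == 3:
        return [
            ScenarioSpec(3, _lin_up(400), _lin_up(c), direction=Direction.POSITIVE, **common)
            for c in POWER_SWEEP
        ]
    if table == 4:
        return [
            ScenarioSpec(4, _lin_down(c), _lin_up(c), direction=Direction.NEGATIVE, **common)
            for c in POWER_SWEEP
        ]
    if table == 5:
        return [
            ScenarioSpec(5, _lin_down(400), _lin_up(c), direction=Direction.NEGATIVE, **common)
            for c in POWER_SWEEP
        ]
    raise ValueError(f"table must be in 1..6, got {table}")
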