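"""Rectangular study windows, grids, point patterns and presence-absence maps.

A presence-absence map records, for every cell of a regular grid laid over a
rectangular study window, whether at least one individual of a species was
observed in that cell.  Maps are the only input the association tests need:
per-cell abundances are deliberately discarded at rasterization.

Cell membership uses half-open intervals ``[lo, hi)`` along each axis, with
the window's upper boundary assigned to the last cell so that the cells
partition the window and no point is lost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Window",
    "GridSpec",
    "PointPattern",
    "PresenceAbsenceMap",
    "rasterize",
    "presence_count",
    "read_grid",
    "write_grid",
]

UNIT_SQUARE_BOUNDS = (0.0, 1.0, 0.0, 1.0)


@dataclass(frozen=True)
class Window:
    """Rectangular study window ``[xmin, xmax] x [ymin, ymax]``."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not self.xmax > self.xmin:
            raise ValueError(f"window requires xmax > xmin, got [{self.xmin}, {self.xmax}]")
        if not self.ymax > self.ymin:
            raise ValueError(f"window requires ymax > ymin, got [{self.ymin}, {self.ymax}]")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside or on the boundary of the window."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)

    @classmethod
    def unit_square(cls) -> "Window":
        return cls(*UNIT_SQUARE_BOUNDS)


@dataclass(frozen=True)
class GridSpec:
    """Regular ``nx`` x ``ny`` grid over a window.

    ``nx`` counts cells along x (columns), ``ny`` along y (rows); the total
    number of cells is ``N = nx * ny``.
    """

    window: Window
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError(f"cell counts must be positive, got nx={self.nx}, ny={self.ny}")
        if self.n_cells < 2:
            raise ValueError("grid must have at least 2 cells")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_width(self) -> float:
        return self.window.width / self.nx

    @property
    def cell_height(self) -> float:
        return self.window.height / self.ny

    @classmethod
    def from_cell_size(cls, window: Window, cell_size: float) -> "GridSpec":
        """Build a grid from a square cell size that must tile the window exactly.

        A 1 x 1 window at ``cell_size=0.05`` yields a 20 x 20 grid (400 cells);
        a 500 x 1000 m window at 5 m yields 100 x 200.  A window that is not an
        integer multiple of the cell size is rejected rather than silently
        truncated, since truncation would change the cell total ``N``.
        """
        if cell_size <= 0:
            raise ValueError(f"cell size must be positive, got {cell_size}")
        nx = window.width / cell_size
        ny = window.height / cell_size
        if abs(nx - round(nx)) > 1e-9 * max(1.0, nx) or abs(ny - round(ny)) > 1e-9 * max(1.0, ny):
            raise ValueError(
                f"window {window.width} x {window.height} is not an exact multiple "
                f"of cell size {cell_size}"
            )
        return cls(window, int(round(nx)), int(round(ny)))


@dataclass(frozen=True)
class PointPattern:
    """Planar point pattern: an (n, 2) coordinate array inside a window."""

    points: np.ndarray
    window: Window
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            pts = np.empty((0, 2), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
        object.__setattr__(self, "points", pts)
        inside = self.window.contains(pts[:, 0], pts[:, 1])
        if not np.all(inside):
            i = int(np.argmin(inside))
            raise ValueError(
                f"point ({pts[i, 0]}, {pts[i, 1]}) lies outside window "
                f"[{self.window.xmin}, {self.window.xmax}] x "
                f"[{self.window.ymin}, {self.window.ymax}]"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class PresenceAbsenceMap:
    """Boolean occupancy grid for one species: ``occupancy[row, col]`` with
    row indexing y and col indexing x."""

    grid: GridSpec
    occupancy: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid "
                f"({self.grid.ny}, {self.grid.nx})"
            )
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_present(self) -> int:
        return int(self.occupancy.sum())

    @property
    def presence_rate(self) -> float:
        return self.n_present / self.grid.n_cells


def rasterize(pattern: PointPattern, grid: GridSpec) -> PresenceAbsenceMap:
    """Convert a point pattern into a presence-absence map.

    A cell is occupied iff at least one point falls in it.  The cell of a
    point is found by ``floor((x - xmin) / cell_width)`` (same for y), with
    points exactly on the window's upper boundary clamped into the last
    cell.  Invariant to point order and to duplicate points.
    """
    if pattern.window != grid.window:
        raise ValueError(
            f"pattern window {pattern.window} does not match grid window {grid.window}"
        )
    occ = np.zeros((grid.ny, grid.nx), dtype=bool)
    if pattern.n_points:
        w = grid.window
        ix = np.floor((pattern.points[:, 0] - w.xmin) / grid.cell_width).astype(int)
        iy = np.floor((pattern.points[:, 1] - w.ymin) / grid.cell_height).astype(int)
        np.clip(ix, 0, grid.nx - 1, out=ix)
        np.clip(iy, 0, grid.ny - 1, out=iy)
        occ[iy, ix] = True
    return PresenceAbsenceMap(grid, occ, pattern.label)


def presence_count(pa_map: PresenceAbsenceMap) -> int:
    """Number of occupied cells (N_a for species a)."""
    return pa_map.n_present


_HEADER_RE = re.compile(
    r"#\s*label=(?P<label>\S*)\s+window=(?P<win>[-0-9.eE+]+,[-0-9.eE+]+,[-0-9.eE+]+,[-0-9.eE+]+)"
)


def write_grid(pa_map: PresenceAbsenceMap, path: str | Path) -> None:
    """Write a map as a whitespace-delimited 0/1 matrix with a header comment
    recording the species label and window bounds."""
    w = pa_map.grid.window
    lines = [f"# label={pa_map.label or 'species'} window={w.xmin},{w.xmax},{w.ymin},{w.ymax}"]
    for row in pa_map.occupancy.astype(int):
        lines.append(" ".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_grid(path: str | Path) -> PresenceAbsenceMap:
    """Read a delimited 0/1 matrix, optionally headed by a ``# label=... window=...``
    comment line.  Without a header the window defaults to the unit square.

    Ragged rows and non-binary entries are rejected with their location.
    """
    path = Path(path)
    label = path.stem
    window = Window.unit_square()
    rows: list[list[int]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            m = _HEADER_RE.match(stripped)
            if m:
                label = m.group("label")
                xmin, xmax, ymin, ymax = (float(v) for v in m.group("win").split(","))
                window = Window(xmin, xmax, ymin, ymax)
            continue
        row = []
        for col, tok in enumerate(re.split(r"[,\s]+", stripped), start=1):
            if tok not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary entry {tok!r} at line {lineno}, column {col}"
                )
            row.append(int(tok))
        if rows and len(row) != len(rows[0]):
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} entries, expected {len(rows[0])})"
            )
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no grid data found")
    occ = np.array(rows, dtype=bool)
    grid = GridSpec(window, nx=occ.shape[1], ny=occ.shape[0])
    return PresenceAbsenceMap(grid, occ, label)
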