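"""Deterministic example datasets for documentation and end-to-end tests.

Three two-species point files are produced on the unit square, mirroring
the canonical illustration setups: an independent uniform pair, a
positively associated pair with shared-direction gradients ``400x`` and
``800x``, and a negatively associated pair with opposed gradients ``400x``
versus ``400(1-x)``.  Matching 20x20 presence-absence grids are written
alongside.
"""

from __future__ import annotations

from pathlib import Path

from .gridmap import GridSpec, Window, rasterize, write_grid
from .pointio import write_points
from .simulate import IntensityFunction, runif_points, rpoispp, split_seed

__all__ = ["make_fixtures"]


def make_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Write the example point files and grids; returns the paths written.

    Regeneration with the same seed reproduces the files bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    window = Window.unit_square()
    grid = GridSpec(window, 20, 20)
    seeds = split_seed(seed, 6)

    datasets = {
        "uniform": {
            "A": runif_points(400, window, seeds[0], "A"),
            "B": runif_points(400, window, seeds[1], "B"),
        },
        "positive": {
            "A": rpoispp(IntensityFunction.parse("400x"), window, seeds[2], "A"),
            "B": rpoispp(IntensityFunction.parse("800x"), window, seeds[3], "B"),
        },
        "negative": {
            "A": rpoispp(IntensityFunction.parse("400x"), window, seeds[4], "A"),
            "B": rpoispp(IntensityFunction.parse("400(1-x)"), window, seeds[5], "B"),
        },
    }
    written: list[Path] = []
    for name, species in datasets.items():
        points_path = out / f"{name}_points.csv"
        write_points(species, points_path)
        written.append(points_path)
        for label, pattern in species.items():
            grid_path = out / f"{name}_{label}.grid"
            write_grid(rasterize(pattern, grid), grid_path)
            written.append(grid_path)
    return written
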