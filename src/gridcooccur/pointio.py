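"""Reading and writing point-pattern files.

Point patterns travel as delimited text with header columns ``x,y`` and an
optional ``species`` column; one file may hold several species.  The
window is not stored in the file and must be supplied by the caller.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gridmap import PointPattern, Window

__all__ = ["read_points", "write_points"]

DEFAULT_SPECIES = "species"


def read_points(path: str | Path, window: Window) -> dict[str, PointPattern]:
    """Read a point CSV/TSV into one :class:`PointPattern` per species.

    Files without a ``species`` column yield a single pattern under the
    default label.  Rows with missing or non-numeric coordinates and points
    outside the window are rejected with their row number.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.argmax(vals.isna().to_numpy()))
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"{path}: non-numeric {col!r} value at line {bad + 2}")
        df[col] = vals
    if "species" not in df.columns:
        df["species"] = DEFAULT_SPECIES
    patterns: dict[str, PointPattern] = {}
    for label, group in df.groupby("species", sort=True):
        pts = group[["x", "y"]].to_numpy(dtype=float)
        inside = window.contains(pts[:, 0], pts[:, 1])
        if not inside.all():
            bad = int(group.index[np.argmin(inside)])
            raise ValueError(
                f"{path}: point at line {bad + 2} lies outside the window "
                f"[{window.xmin}, {window.xmax}] x [{window.ymin}, {window.ymax}]"
            )
        patterns[str(label)] = PointPattern(pts, window, str(label))
    return patterns


def write_points(patterns: dict[str, PointPattern] | PointPattern, path: str | Path) -> None:
    """Write one or more point patterns as a CSV with columns x,y,species."""
    if isinstance(patterns, PointPattern):
        patterns = {patterns.label or DEFAULT_SPECIES: patterns}
    frames = [
        pd.DataFrame(
            {"x": p.points[:, 0], "y": p.points[:, 1], "species": label or DEFAULT_SPECIES}
        )
        for label, p in patterns.items()
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["x", "y", "species"]
    )
    out.to_csv(path, index=False, float_format="%.10g")
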