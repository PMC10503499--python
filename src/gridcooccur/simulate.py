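"""Point-process simulators: uniform patterns and inhomogeneous Poisson
patterns with linear intensity gradients on a rectangular window.

Positive association between two simulated species is induced by giving
both a shared spatial gradient (e.g. intensity ``c*x`` for both); negative
association by opposed gradients (``c*x`` vs ``c*(1-x)``).  Placements are
conditionally independent given the intensities, so the association is
environmental rather than interactive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .gridmap import PointPattern, Window

__all__ = ["IntensityForm", "IntensityFunction", "runif_points", "rpoispp", "split_seed"]


class IntensityForm(enum.Enum):
    CONSTANT = "constant"
    LINEAR_X_INCREASING = "linear_x_increasing"
    LINEAR_X_DECREASING = "linear_x_decreasing"


@dataclass(frozen=True)
class IntensityFunction:
    """First-order intensity λ(x, y) in expected points per unit area.

    ``constant``: λ = c; ``linear_x_increasing``: λ = c*x;
    ``linear_x_decreasing``: λ = c*(1 - x).
    """

    form: IntensityForm
    c: float

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"intensity coefficient must be positive, got {self.c}")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form is IntensityForm.CONSTANT:
            return np.full_like(x, self.c)
        if self.form is IntensityForm.LINEAR_X_INCREASING:
            return self.c * x
        return self.c * (1.0 - x)

    @property
    def maximum(self) -> float:
        """Upper bound of λ on the unit square (the thinning envelope)."""
        return self.c

    def integral(self, window: Window) -> float:
        """Expected total point count over the window."""
        if self.form is IntensityForm.CONSTANT:
            return self.c * window.area
        # mean of c*x (or c*(1-x)) over the window times its area
        xbar = (window.xmin + window.xmax) / 2
        if self.form is IntensityForm.LINEAR_X_DECREASING:
            xbar = 1.0 - xbar
        return self.c * xbar * window.area

    @classmethod
    def parse(cls, text: str) -> "IntensityFunction":
        """Parse compact forms like ``400``, ``400x`` or ``400(1-x)``."""
        s = text.strip().replace(" ", "").replace("*", "")
        if s.endswith("(1-x)"):
            return cls(IntensityForm.LINEAR_X_DECREASING, float(s[:-5]))
        if s.endswith("x"):
            return cls(IntensityForm.LINEAR_X_INCREASING, float(s[:-1]))
        return cls(IntensityForm.CONSTANT, float(s))

    def __str__(self) -> str:
        c = f"{self.c:g}"
        if self.form is IntensityForm.CONSTANT:
            return c
        if self.form is IntensityForm.LINEAR_X_INCREASING:
            return f"{c}x"
        return f"{c}(1-x)"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def split_seed(seed, n: int) -> list[np.random.SeedSequence]:
    """Spawn ``n`` independent child seed sequences from a root seed.

    Children are statistically independent streams, so replicates (and the
    two species within a replicate) can be simulated reproducibly yet
    without shared randomness.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return root.spawn(n)


def runif_points(n: int, window: Window, seed=None, label: str = "") -> PointPattern:
    """Exactly ``n`` points placed independently and uniformly in the window."""
    if n < 0:
        raise ValueError(f"n must be nonnegative, got {n}")
    rng = _as_rng(seed)
    x = rng.uniform(window.xmin, window.xmax, size=n)
    y = rng.uniform(window.ymin, window.ymax, size=n)
    return PointPattern(np.column_stack([x, y]), window, label)


def rpoispp(
    lam: IntensityFunction, window: Window, seed=None, label: str = ""
) -> PointPattern:
    """Inhomogeneous Poisson pattern by Lewis–Shedler thinning.

    A homogeneous candidate pattern with intensity ``λ_max`` is drawn
    (count ~ Poisson(λ_max * area), uniform positions) and each candidate
    is retained with probability ``λ(x, y) / λ_max``.  The retained count
    is Poisson with mean ``∫λ``; for the constant form no candidate is
    rejected.
    """
    rng = _as_rng(seed)
    lam_max = lam.maximum
    n_cand = rng.poisson(lam_max * window.area)
    x = rng.uniform(window.xmin, window.xmax, size=n_cand)
    y = rng.uniform(window.ymin, window.ymax, size=n_cand)
    keep = rng.uniform(size=n_cand) < lam(x, y) / lam_max
    return PointPattern(np.column_stack([x[keep], y[keep]]), window, label)
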