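# Methods

## Model and null hypothesis

The study plot is a rectangle `W` divided into a regular grid of `N`
cells; the data for one species is the boolean occupancy of each cell
(presence-absence map). For a species pair, the 2×2 table counts cells
with both species (`o1`), neither (`o2`), only A (`o3`), only B (`o4`);
`Na = o1+o3` and `Nb = o1+o4` are the marginal presence totals.

The null model ("random association") is that every individual of either
species is placed in any cell with equal probability, independently of
everything else. Under it the expected counts are `E1 = Na·Nb/N`,
`E2 = (N−Na)(N−Nb)/N`, `E3 = Na(N−Nb)/N`, `E4 = (N−Na)·Nb/N`
(these sum to `N` and satisfy `E1·E2 = E3·E4`), and each observed count
is marginally `Oi ~ Bin(N, Ei/N)`; for large `N` with small `Ei/N`,
`Oi ≈ Poi(Ei)` and `Oi + Oj ≈ Poi(Ei + Ej)`.

## The tests

**Chi-squared.** `Σ(oi − Ei)²/Ei` against `χ²(1)`. When any `Ei < 10`
each deviation is continuity-corrected: `(|oi − Ei| − 0.5)²/Ei`, with the
term clamped to zero when 0.5 exceeds the deviation. The `Ei < 10`
trigger is deliberately stricter than the conventional `< 5`. The test is
two-sided: it detects non-independence but not its sign.

**Directional tail tests P1–P6.** Positive association makes `O1` and
`O2` large and `O3`, `O4` small; negative association the reverse. Each
test reports an inclusive tail probability of its count statistic under
the null law above: P1 and P4 use `O1` (binomial vs Poisson), P5 uses
`O1+O2`, P6 uses `O3+O4`, and P2 and P3 multiply the two marginal tails
of `(O1, O2)` and `(O3, O4)` respectively. The negative direction flips
every inequality. Because the tails are inclusive,
`p_pos + p_neg = 1 + P(O = o)` for every scalar statistic.

P2/P3 treat their two components as independent although the multinomial
counts are negatively correlated (`Cov(Oi, Oj) = −Ei·Ej/N`). This is a
deliberate modeling choice, not an oversight: when either expected count
is small — very low or very high presence rates — the correlation is
negligible and the product approximation is nearly exact, which is
precisely where P2 keeps its size near nominal and dominates the
alternatives in power. The exact joint version is intentionally not
substituted, since the documented power behaviour depends on the product
form.

**P7 (Veech's probabilistic method).** Conditioning on both presence
totals, the co-occurrence count follows the hypergeometric law of the
2×2 table with fixed margins, supported on
`max(0, Na+Nb−N) ≤ j ≤ min(Na, Nb)`; the p-value is the inclusive tail
at `o1`. It is computed from the combinatorial form via log-gamma
arithmetic, so grids of tens of thousands of cells (e.g. a 5 m grid on a
50-ha plot, `N = 20 000`) do not overflow; tests cross-check it against
an independent hypergeometric implementation and brute-force subset
enumeration.

**Rejection rule.** A test rejects when `p ≤ α` (not strict `<`);
`α = 0.05` everywhere by default.

## Degenerate inputs

If a species is present in every cell or in none, some `Ei = 0`: the
chi-squared statistic is undefined and raises (or is reported as missing
by the pair runner, with a warning); the tail tests remain total — a null
distribution that is a point mass at zero gives tails of exactly 0 or 1,
which scipy's distributions handle directly. Pair reports carry a
`degenerate` flag so downstream consumers can filter.

## Rasterization conventions

Cells are half-open boxes `[lo, hi)` in both axes, with the window's
upper boundary assigned to the last cell, so the cells partition the
window and every point maps to exactly one cell. Rasterization is
invariant to point order and duplicates. Grids may be specified by cell
counts or by a square cell size; the cell size must tile the window
exactly (an inexact size is an error rather than a silent truncation,
which would change `N`).

## Simulators

`runif_points(n, window, seed)` places exactly `n` independent uniform
points. `rpoispp(λ, window, seed)` draws an inhomogeneous Poisson pattern
by Lewis–Shedler thinning: a homogeneous candidate set with intensity
`λ_max` (count `~ Poi(λ_max·area)`, uniform positions) is thinned by
keeping each point with probability `λ(x,y)/λ_max`. Thinning is exact —
no discretization bias — and for the linear forms `λ = c·x` and
`c·(1−x)` the envelope is simply `λ_max = c`. Supported intensity forms
are constant and the two linear-in-x gradients; expected totals on the
unit square are `c` and `c/2` respectively.

Association between two simulated species is induced *environmentally*:
shared gradients (both `c·x`) produce positive association, opposed
gradients (`c·(1−x)` vs `c·x`) negative association, while placements
remain conditionally independent given the intensities. No interactive
(cross-correlated) mechanism is modeled.

Randomness is driven by numpy `SeedSequence` spawning: one root seed
spawns per-replicate children, and each replicate spawns one substream
per species, so replicates are independent yet bit-reproducible.

## Simulation study

The default study conditions are the unit-square window with a 20×20
grid (400 cells of size 0.05), 500 replicates per condition, `α = 0.05`:

- Scenario 1 (null): two independent uniform patterns with equal
  abundance, swept over 20, 40, 100, 200, …, 1000 points. Rejection
  proportions estimate type-I error; mean occupied-cell counts follow the
  closed form `N(1 − (1 − 1/N)^n)`.
- Scenario 2: both species share intensity `c·x`, `c` swept over
  100–1000 by 100 and 2000–5000 by 1000 (positive association, similar
  presences).
- Scenario 3: species A fixed at `400x`, B swept (dissimilar presences).
- Scenario 4: A at `c(1−x)` vs B at `c·x` (negative association).
- Scenario 5: A fixed at `400(1−x)`, B swept.

All seven tests (plus chi-squared) are scored on the *same* replicate
data within a scenario, which removes between-method Monte-Carlo noise
from power comparisons and makes two orderings hold replicate-by-
replicate: the extra tail factor in P2 can only shrink the p-value, so
P2's rejections contain P1's; and in the rejection region the binomial
upper tail is lighter than the Poisson's, so P1's rejections contain
P4's.

Rejection-proportion estimates over `R` replicates carry binomial
Monte-Carlo error; comparisons in the test suite use a
`3·sqrt(p(1−p)/R)` tolerance. The replicate count is configurable; the
acceptance script and acceptance tests use the full `R = 500`, which
runs in seconds per condition at these problem sizes.

## What the simulations do and do not show

The generators emulate smooth first-order intensity gradients on a small
plot. Real presence-absence data additionally exhibit clustering from
dispersal or habitat patchiness (the tests here have no spatial context
beyond the contingency table), false absences, and observation error —
none of which are modeled. Passing the study reproductions therefore
validates the statistical machinery under the stated point-process
conditions, not robustness to spatially structured residual correlation.

Method choice guidance surfaced by the CLI advisory: within presence
rates of roughly 22.5–85% the fixed-margins test P7 (or P3) keeps its
size below nominal with near-top power; outside that band — very sparse
or near-saturated maps — P2 is preferred, with size closest to nominal
and the highest power. The advisory is informational; all p-values are
always reported.

## Known limitations

- P2/P3 can exceed the nominal size at moderate presence rates (the
  product approximation ignores negative correlation there); use the
  advisory band.
- The chi-squared test is conservative at extreme presence rates
  (type-I error well below 5% for abundances outside ~200–700 on the
  default grid).
- Only rectangular windows and regular grids are supported; no
  geographic projections or raster formats.
- No multiple-testing correction is applied across species pairs; raw
  p-values are reported.
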