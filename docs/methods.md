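# Methods

## Problem and model

`spatialaq` analyses point-referenced sensor observations (x, y, value) in
two stages: (1) choose a spatial aggregation scale whose areal summary
best expresses the spatial structure of the data, and (2) interpolate the
field between sensors with kriging. The observation variable is typically
a pollutant's Air Quality Index, but nothing in the pipeline is specific
to air quality except the AQI module.

### Projection

Geographic coordinates are projected with an equirectangular projection
about the data centroid: x = R·cos(lat₀)·Δlon·π/180, y = R·Δlat·π/180,
with R = 6378.137 km (WGS84 equatorial radius). The projection is exactly
invertible and kilometre-true along the origin parallel; cell areas are
approximate away from it, which is acceptable at the few-hundred-km desk
scale the method targets. A different origin can be supplied; an
equal-area projection can be slotted in through the same interface if a
study demands exact areas.

### Hexagonal areal units

The study window (bbox of the projected points) is tessellated with
regular flat-top hexagons of side *s* (pointy-top available; flat-top is
the fixed default for reproducibility). The lattice is anchored with a
cell centre at the bbox lower-left corner. The anchor is itself a
MAUP-relevant choice — shifting it changes every aggregate — so it is
exposed rather than hidden. Cells are Voronoi regions of the centre
lattice, so point assignment is nearest-centre; boundary ties go to the
cell whose centre is lexicographically smallest in (x, y), making the
assignment a deterministic partition. Cells with fewer than `min_count`
points (default 1) carry no value and are excluded from the weights graph.
Cells crossing the window edge are not clipped to any land boundary.

### Moran statistics

First-order contiguity over hexagons: two cells are neighbours iff they
share an edge, equivalently iff their centres are exactly √3·s apart (for
hexagons, rook and queen contiguity coincide). Weights are binary or
row-standardized; row-standardized is the default used by the scale
objectives. Isolated cells are flagged, keep a zero spatial lag, and stay
in *n*.

Global Moran's I and the local decomposition I_i are computed exactly from
their defining sums; the mean ȳ is the mean over aggregated cells, not
over raw sensors. Under row standardization Σᵢ Iᵢ = n·I, so mean(Iᵢ) = I —
this identity is asserted in the tests at 1e-10 as an internal consistency
oracle.

Inference is by conditional permutation. Global: the values are permuted
wholesale 999 times (default) and p = (1 + #{|I_perm| ≥ |I_obs|})/(1 +
permutations), two-sided. Local: y_i is held fixed while random
k_i-subsets of the remaining values are placed on cell i's neighbours.
All permutation draws flow through a caller-supplied seed. Quadrants
(HH/LL/HL/LH) follow the signs of the deviation and the lag; cells with
p > 0.05 are labelled not-significant.

The instability objective is CV = sd(Iᵢ)/|mean(Iᵢ)| with the sample
standard deviation (n−1). The absolute value in the denominator keeps the
objective's sign stable when the mean is near zero; an exactly zero mean
returns +∞ with a warning (such a scale can then never win on this
objective, which is the intended reading of "maximally unstable"). All
local values enter the CV — no significance pre-filtering — because
filtering would couple the objective to the permutation sample.

### Pareto scale selection

Candidates are the user-supplied scale list. Dominance: a dominates b iff
a is at least as good in both objectives (GM to maximize, LMCV to
minimize) and strictly better in one. Iterative non-dominated sorting
assigns frontier ranks; the rank-1 set is returned whole — ties are a
finding, not something to break automatically. Dominance operates on raw
objectives; the min–max rescaling of LMCV into the GM interval exists only
for chart output (monotone per-objective transforms cannot change
dominance). Scales that yield fewer than 3 non-empty cells, an
all-isolated graph or constant aggregates are dropped with a warning.

### Geostatistics

Values are normalized before variography. The normalizer tries identity,
log(x+ε), square root, Box–Cox, Yeo–Johnson and a rank-based
ordered-quantile transform, and keeps the one with the highest
Shapiro–Wilk W. Every candidate is exactly invertible on the observed
range (the ordered-quantile inverse interpolates the fitted rank curve,
exact at observed values). Fewer than 10 values, or constant input, fall
back to identity with a warning.

Empirical variogram: Matheron estimator on 15 equal-width lag bins
(default) up to half the maximum pairwise distance; empty bins are
dropped, thin bins flagged. Model fitting is weighted least squares with
pair-count weights and non-negativity bounds on (c₀, c, a); the
exponential form is γ(h) = c₀ + c·(1 − e^(−h/a)), so the *practical*
range (95% of the sill) is ≈ 3a. When the fitted curve expresses
negligible structured variation over the observed lags the fit collapses
to pure nugget with a warning — the range is unidentifiable there, and
the optimizer may otherwise park it at either bound.

Ordinary kriging solves the bordered semivariance system (Lagrange
multiplier enforcing Σλ = 1) with one LU factorization shared across all
targets; a moving-neighbourhood mode (k nearest observations per target)
is available for large datasets. γ(0) = 0 exactly, so the predictor
interpolates the data exactly; duplicate locations make the system
singular and raise an error with deduplication guidance. The kriging
variance is reported on the transformed scale only — the nonlinear
back-transform of a variance has no simple closed form, and pretending
otherwise would be worse than documenting the limitation. Point estimates
are back-transformed.

Indicator kriging maps exceedance probability: values become 1{z > t},
the indicator variogram is fitted, indicators are kriged and estimates
clipped into [0, 1]. The showcase threshold is AQI 50, the Good/Moderate
boundary. If every observation sits on one side of the threshold the
surface is that constant, with a warning.

### AQI

I_P = (I_Hi − I_LO)/(BP_Hi − BP_LO)·(C_P − BP_LO) + I_LO on the breakpoint
row containing the truncated concentration C_P (truncation, not rounding,
to the pollutant's reporting precision), final index rounded half-up. The
shipped breakpoint JSON carries the published US-EPA technical-assistance
values for O3 (8-h ppm), CO (8-h ppm), SO2 (1-h ppb) and NO2 (1-h ppb);
any table in the same schema can be substituted. The six categories
(Good … Hazardous) partition [0, ∞) with integer bounds. The daily-table
reader can either use the pollutant's reported AQI column (default) or
its mean concentration for recomputation through this module.

## Synthetic data

The generator draws locations uniformly in a planar box and values
jointly from a zero-mean stationary Gaussian process with exponential
(C(h) = sill·e^(−h/a)), Gaussian, or pure-nugget covariance, plus
independent nugget noise and a constant mean — i.e. exactly the class of
fields the variogram model assumes. Defaults: 1000 × 1000 km window, 300
points, exponential covariance with a 200 km range, unit sill, zero
nugget — a continental-scale monitoring network with a correlation length
between the method's coarser and finer candidate scales. Sampling is by
dense Cholesky factorization with a jitter ladder, capped at 4000 points.
One seeded `numpy` Generator drives locations and values; identical specs
give bit-identical fields.

What the generator does *not* emulate: non-stationarity (trends, coastal
effects), preferential sensor placement near cities, temporal dynamics,
and non-Gaussian marginals beyond what the normalizer can absorb. Tests
passing on these fields therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to real-world
violations of them.

The checkerboard fixture (±1 on a rook-adjacent square lattice) provides
the negative-autocorrelation ground truth: the 2×2 board is the 4-cycle
graph with I = −1 under binary weights.

## Numerical choices

- Hexagon adjacency uses a √3·s centre-distance criterion with 1e-6
  relative tolerance; the geometric shared-edge test is kept as a test
  oracle only.
- Permutation p-values use a 1e-14 slack on the ≥ comparison so that
  exact ties (common on lattice fixtures) count as extreme.
- Kriging variances are clipped at zero against roundoff; weight sums are
  verified to 1e-10 in the tests.
- Cross-validation and acceptance runs use 300-point fields and ≤ 500
  prediction nodes — sizes at which the dense solvers are exact and the
  full suite runs in seconds.

## Limitations

- The equirectangular frame distorts area at continental extents; scale
  selection is unaffected (all candidates share the frame) but reported
  cell areas are nominal.
- The permutation test is simple conditional randomization; analytic
  moments of Moran's I under normality are not implemented.
- Kriging assumes a constant unknown mean (ordinary kriging); trends must
  be removed upstream. Simple kriging and co-kriging are out of scope.
- The CV objective degenerates (infinite) when the mean local Moran is
  zero; such scales are effectively excluded by dominance.
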