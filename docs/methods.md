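# Methods

`rangeselect` implements a suite of eight home-range estimators for animal
telemetry, an ROC/AUC goodness-of-fit statistic for choosing among them, the
statistical comparison machinery for multi-animal studies, and a synthetic
telemetry generator so the whole pipeline runs without field data.  This
note records the models, the numerical choices, and the places where the
design was genuinely open.

## The shared raster surface

Everything operates in a projected planar CRS in meters.  For each animal a
single reference grid (default grain 100 m) is built once and reused by
every estimator, so AUC compares estimators on an identical grain and
extent.  The grid's lower-left corner is `(min - buffer)` snapped down to a
multiple of the grain; the buffer defaults to 3 grains per side, which keeps
kernel mass loss off-grid negligible at this grain (losses above 0.1% are
reported as warnings).  Cells are half-open in both axes — every in-extent
point belongs to exactly one cell, and points exactly on the max edge belong
to the last cell.

A utilization distribution (UD) is a per-cell probability mass.  Its volume
contour level for a cell is 100 × (total mass of all cells at least as
heavy); tied masses are grouped before accumulating so ties share one level,
which is exactly the tie handling the rank-sum AUC needs.  The L% isopleth
is the union of positive-mass cells with level ≤ L, polygonized along cell
edges.

## Hull-family estimators (LOCO, SLCA, CHAR)

All three build an ordered sequence of small polygons, union them
progressively, and read isopleths off the percent of relocations covered by
each prefix.  Cells are scored `100 − (smallest covering percent level)`,
with −∞ outside the 100% region; AUC only uses ranks, so any monotone
mapping is equivalent.

* **k-LoCoH** — per relocation, the convex hull of the point plus its k−1
  nearest neighbours, k = round(√n) by default (minimum 3); hulls sorted by
  area ascending, ties broken by point index.  Duplicate points are retained
  and produce zero-area hulls that legitimately sort first.
* **SLCA** — clusters grown from triples.  The step rule had to be
  concretized: each iteration executes the globally cheapest of three moves
  — *join* (attach an unassigned point to a cluster; cost = mean distance to
  the min(3, |cluster|) nearest members), *merge* (fuse two clusters; cost =
  mean of the 3 smallest inter-cluster distances), and *seed* (start a new
  cluster from a point and its two nearest unassigned neighbours; cost =
  mean pairwise distance of the triple).  Ties break by move type
  (join < merge < seed), then index.  The incremental implementation is
  verified against a brute-force oracle that recomputes every cost from the
  definitions each step.  The isopleth at P% is the union of per-cluster
  convex hulls over the first ⌈P%·n⌉ assigned points.
* **CHAR** — Delaunay triangles ordered smallest to largest; the isopleth at
  P% is the shortest prefix covering ≥ P% of points.  The 100% level is
  *all* triangles, which equals the MCP exactly (coverage reaches 100%
  before the last triangles are added, so this level is special-cased).

## Kernel estimators (LKDE, PKDE, LSCV)

* **LKDE** uses the ad hoc normal-reference bandwidth
  h = √((s²x + s²y)/2) · n^(−1/6) (sample SDs, ddof = 1).
* **PKDE** is a two-stage bivariate plug-in returning a full SPD bandwidth
  matrix.  The data are sphered; sixth-order density-derivative functionals
  are taken at their normal reference and define an AMSE-style scalar pilot
  g = (16/(3n))^(1/8); the five fourth-order functionals are then estimated
  empirically with that pilot, and the asymptotic MISE
  `(4πn)⁻¹|H|^(−1/2) + ¼ vec-quadratic(H)` is minimized over SPD matrices
  via a deterministic Nelder–Mead search in log-Cholesky coordinates started
  at the normal-reference matrix.  Sphering makes the selector affine
  equivariant; on Gaussian data the result lands within a few percent of the
  normal-reference optimum n^(−1/3)Σ.
* **LSCV** minimizes the cross-validation score over h ∈
  [h_ref/100, 10·h_ref] (grid scan plus bounded refinement).  Heavily
  duplicated relocations drive the objective to −∞ as h → 0; a minimum
  within 10⁻³ (relative) of the lower edge is returned as a *declared
  failure*, never as a bandwidth — reproducing the known unusability of
  LSCV on GPS datasets with many duplicate fixes.

Kernels are evaluated at cell centers (not integrated over cells); at
100 m grain and the movement scales targeted here the difference is
negligible.  Kernel evaluation is truncated at 8 SDs, which perturbs masses
far below the 10⁻⁹ tolerances used in tests.

## Bridge estimators (BBMM, dBBMM, MKDE)

The BBMM links successive fixes with conditional Brownian bridges.  The
motion variance σ²m (m²/s) is estimated by leave-one-out likelihood:
alternate fixes (positions 0, 2, 4, …) are bridge endpoints and the interior
fixes are scored against a bivariate normal centered on the linear
interpolation with per-axis variance

    T·a·(1−a)·σ²m + (1−a)²δ₁² + a²δ₂² + δ_mid²,

where T is the bracketing interval, a the relative time, δ₁/δ₂ the
endpoint location-error SDs and δ_mid the scored fix's own.  Including
δ_mid is the full predictive variance of an *observed* middle fix; selectors
that omit it inflate σ̂²m by δ²/(T·a(1−a)) — a 3× bias at GPS error scales
and hourly sampling — so this package includes it.  The likelihood is
maximized by bounded 1-D search on log σ²m, with the σ²m = 0 boundary
checked explicitly.

UDs average each bridge's density over interior quadrature points (midpoint
rule, default 10 per segment), weight segments by duration, and normalize.

The **dBBMM** slides a window (default 31 fixes, margin 11) along the path.
Within each window a single-variance model competes by BIC against
two-variance models split at admissible breakpoints.  Two structural
choices matter: breakpoints are restricted to bridge endpoints (even window
offsets) so that all candidate models score the identical leave-one-out fix
set (an odd split changes the pairing parity, silently drops an observation
and wins the comparison spuriously); and the split models count k = 3
parameters (two variances plus the estimated breakpoint location, the usual
changepoint convention).  Each non-margin fix receives the average of the
selected-model variances from all windows covering it; leading/trailing
margins inherit the nearest interior value.  With the default window the
per-window variance MLE rests on ~15 scored fixes (relative SD ≈ 26%), so
on a homogeneous track roughly 80% of per-fix variances fall within ±30% of
the global estimate — that is the sampling-noise floor, not an estimation
defect.  A constant variance sequence reproduces the BBMM UD exactly.

**MKDE** (biased random bridges): segments longer than Tmax (default 12 h)
are skipped; segments shorter than Lmin (default 5 m) place stationary
kernels of SD hmin at their endpoints; all others are interpolated roughly
every τ seconds (default 300 s), the point at relative time p carrying a
normal kernel with h²(p) = hmin² + 2·p(1−p)·D·T.  The factor 2 in the
bridge-shaped inflation is a committed constant isolated in one function
(`brb_smoothing_sq`) so it can be revised in one place.  hmin defaults to
34 m (GPS error scale); the diffusion D defaults to the method-of-moments
estimate mean(d²/(4T)).  A track with no usable segment — the typical
aerial-VHF case with days between fixes — raises a declared
`MkdeNotEstimableError` rather than returning a surface.

## The AUC statistic

Response: binary presence per cell (a cell with ten fixes counts once —
multiplicity already shaped the estimator, not the response).  Predictor:
the estimator's cell score.  AUC is the tie-corrected rank-sum statistic
(wins + half-ties over n₁·n₀), computed exactly via midranks; it equals the
trapezoidal ROC area and is invariant under strictly increasing transforms
of the score field.  Grids with all cells occupied (or none) make AUC
undefined and raise.

## Statistical comparison

Mixed models are fit to logit-AUC of GPS records with a single animal
random intercept; AUC exactly 1 (possible for hull estimators on tiny
grids) is clamped to 1 − 1/(2·n_cells) with a warning.  The fit profiles
the REML criterion over the variance ratio λ = σ²animal/σ²resid with the
λ = 0 boundary evaluated explicitly, so zero between-animal variance
reduces exactly to OLS.  Coefficients, SEs and Wald 95% CIs come from the
REML fit; the log-likelihood used for AICc is the ML profile optimum,
because REML likelihoods are not comparable across fixed-effect structures.
K counts fixed effects plus the two variance parameters — this reproduces
the published parameter counts for the categorical models (estimator-only:
7 dummies + intercept + 2 = 10).  The a priori 12-model set combines
estimator type, fix success, GPS schedule, number-of-locations class
(bins ≤100, 101–500, 501–1000, >1000) and study area; SLCA is the
estimator reference level; covariates with a single observed level are
dropped with a warning.  Akaike weights are exp(−δ/2) normalized; models
with δ < 4 are flagged as candidates.  Group-level contrasts use
Kruskal–Wallis (tie-corrected, χ² approximation) over technology ×
estimator groups and Bonferroni-adjusted pairwise Welch t-tests.
statsmodels' MixedLM serves as an independent cross-check in the test
suite, not as the implementation.

## Synthetic telemetry

Movement is an Ornstein–Uhlenbeck process — stationary and mean-reverting,
so each simulated animal has a true long-run range — sampled with the exact
discrete transition at arbitrary time steps (cohorts are simulated exactly
at the union of their GPS attempt times and VHF flight times, so both
technologies observe one underlying path).  Defaults: stationary SD 3 km
per axis and a 2-day reversion time scale, giving RMS hourly displacements
near 600 m — strongly autocorrelated hourly tracks consistent with
large-felid daily travel.  The observation layer emulates the field
protocols the package benchmarks against: GPS duty cycles of 1 h / 4 h /
7 h with 74% per-attempt fix success and 34 m isotropic error; aerial VHF
as one fix per Monday/Wednesday/Friday morning (0700–1100, UTC treated as
local) with 124 m error and detection probability 0.67, reproducing the
~105 fixes/year annual VHF regime out of 156 scheduled flights.  Dropout
decisions are drawn before measurement errors, so changing only the error
SD leaves timestamps unchanged.  Per-animal seeds derive deterministically
from the master seed.

What the generator does *not* emulate: habitat-dependent movement, hard
range boundaries, diel activity cycles, collar-brand differences, or
temporally clustered fix failure.  Passing tests therefore demonstrate
correct estimator behaviour under an idealized home-ranging process, not
performance on real landscapes.

## Problem sizes used in the shipped checks

The full-pipeline benchmark simulates 10 animals for 126 days (18 weeks):
hourly GPS yields ≈ 2,200 fixes/animal and VHF ≈ 35, enough for the dBBMM
window on most VHF tracks while keeping the suite's runtime modest; VHF
tracks that fall under the window produce honest per-record failures.
Parameter-recovery checks use 400–500-fix tracks over 20 seeds; the
mixed-model recovery simulates 31 animals (the cohort size of the study
design this package emulates) over 50 seeds.  The acceptance script's
pipeline target uses 3 animals at the 7-hour schedule over 180 days.

## Known limitations

* SLCA's step rule is one concretization of a loosely specified clustering
  procedure; other published variants order assignments differently.
* The BRB variance-inflation constant and the plug-in pilot are committed
  package choices within their method families.
* ESRI ASCII and GeoJSON are the only output formats; input must already be
  in a projected meter CRS (geographic-looking coordinates are refused with
  guidance).
* Wald CIs from the mixed model ignore uncertainty in the variance ratio;
  with few animals they undercover slightly.
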