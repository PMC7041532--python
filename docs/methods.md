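# Methods

This note documents the models, the numerical choices and the design
decisions behind `trackthin`, and what the synthetic cohort does and does
not establish about real tracking data.

## Tracks, projection, legs

A track is an ordered sequence of timestamped GPS fixes for one follow.
Timestamps arrive at integer-second resolution but are carried as real
seconds internally, because interpolation produces fractional times.
Geographic coordinates (WGS84) are projected to a local metric plane with
an equirectangular projection about the per-track centroid,
x = R·(λ−λ₀)·cos φ₀·π/180, y = R·(φ−φ₀)·π/180, R = 6 371 000 m. For
tracks spanning a few kilometres this is within 0.01 % of geodesic
distances (verified against a haversine oracle in the tests) and is exactly
invertible, which the synthetic round-trip tests exploit. A track spanning
more than 1° of latitude triggers a warning; no UTM or ellipsoidal geodesy
is attempted. Elevation, if present in the input, is ignored: path lengths
are planar.

Legs are the segments between consecutive fixes (duration, Euclidean
displacement). A track is excluded from analysis when any leg exceeds the
gap threshold (default 60 s). The boundary is inclusive — a leg of exactly
60 s is retained — because quasi-continuous recording at a nominal ~19 s
cadence legitimately produces 60 s legs, and only gaps *beyond* the
device's worst regular spacing indicate an interrupted follow.

## Re-discretisation and deviation

Resampling places grid times t₀, t₀+Δ, … up to the last grid point at or
before the final fix; each grid position is the linear interpolation in
time between the bracketing fixes, in the metric frame (not in lon/lat),
matching the metric in which path length is measured. By default the
original terminal fix is appended when it is off-grid, so original and
resampled tracks span the same [t₀, t_N] and deviations are comparable
across intervals; the appended leg is negligible for 2 h tracks that
overshoot a round duration by seconds. A flag restores strict-grid
truncation. The grid is anchored at the track's first timestamp; nothing
in the problem suggests wall-clock anchoring, and anchoring at t₀ makes
resampling idempotent.

Deviation is reported in percent of the original length. Since every
resampled vertex lies on the original polyline, the resampled length can
never exceed the original (triangle inequality), so deviation ∈ [0, 100] %;
refining a grid to a superset of time points can only recover length, so
deviation is monotone along divisor chains (both facts are asserted as
invariants in the tests). A stationary track has zero original length and
its deviation is undefined; such tracks are reported separately rather
than assigned a value.

## Descriptive statistics

Box summaries use quartiles by linear interpolation of order statistics
(type 7, the default of mainstream statistical software; the convention is
configurable since median deviations are the headline numbers) and Tukey
whiskers clipped to the observed range: upper = min(max x, Q3+1.5·IQR),
lower = max(min x, Q1−1.5·IQR). The Kruskal–Wallis statistic is computed
from mid-ranks with the tie-correction divisor 1 − Σ(t³−t)/(N³−N); it is
checked against both a naive mid-ranking implementation and
`scipy.stats.kruskal`. The p-value is the upper χ² tail at k−1 degrees of
freedom. With every observation identical, H is defined as 0.

## The deviation-curve model

The response is the shifted deviation y − c with default c = −15, i.e. the
model acts on y + 15. The shift keeps the response strictly positive for
every non-negative deviation while preserving the saturating-curve shape
on the original scale; the alternative direction (modelling y − 15) is
selectable but fails whenever deviations below 15 % occur, which is the
norm at 1–2 min intervals, so it is not the default. The linear predictor
is β₀ + β₁t + β₂log t with t in minutes on [1, 120], plus a Gaussian
random intercept per track that absorbs between-track differences in
tortuosity.

Estimation maximises the exact marginal likelihood: with a single random
intercept the per-track covariance is compound-symmetric, σ²I + τ²J,
inverted in closed form (Woodbury), fixed effects profiled out by GLS, and
the two variance parameters optimised by L-BFGS-B on (log σ, log τ). No
sampling is involved, so the fit is deterministic and reproducible to
machine precision; a seed argument exists only for interface uniformity.
The marginal likelihood is verified against adaptive quadrature over the
random intercept on small instances, and the full fit against
`statsmodels` MixedLM (ML). τ collapsing below 10⁻³σ is flagged as a
singular fit rather than an error. Per-track intercepts are reported as
BLUPs, τ²·Σrᵢ/(σ²+nᵢτ²).

The reported curve is the population expectation with γ marginalised,
E[y|t] = c + exp(η(t) + (σ²+τ²)/2); its point-wise band propagates
fixed-effect uncertainty through η by the delta method at the configured
level (default 99 %), with the variance components plugged in. Predictor
sets are compared by exact leave-one-track-out log predictive density
(each track's marginal Gaussian density under a fit to the remaining
tracks) — affordable at ~50 tracks — with AIC as a fast alternative; ties
break toward fewer parameters.

## The movement HMM

Observations on the 5-min grid are step lengths and turning angles. The
5-min grid is the compromise scale: long enough that steps accumulate
measurable deviation, short enough that a grid cell rarely mixes latent
states. Angles are signed heading changes, counter-clockwise positive,
wrapped to (−π, π]; an angle adjacent to a zero-length step is undefined
and treated as missing (likelihood 1), the standard movement-HMM
convention. Step emissions are zero-inflated gamma — a point mass at
exactly zero lets the resting state emit no movement without a degenerate
density — and angle emissions are von Mises with mean fixed at 0 (the
states are characterised by straightness, not by a preferred turn
direction; the mean can be freed). The uniform-turning state is the
κ → 0 limit, reached by estimation rather than constraint.

The likelihood is the forward recursion in log space (no underflow at any
realistic T), restarted from the initial distribution for each track and
summed across tracks. It is verified against explicit enumeration of all
3^T paths for T ≤ 8. Fitting maximises this likelihood directly with
L-BFGS-B over an unconstrained reparameterisation: log step mean/SD,
logit zero-mass, log κ, multinomial-logit transition rows (diagonal logit
fixed at 0) and initial distribution — so transition rows and the initial
vector are simplex-valued by construction at every iterate. Bounds of
±15 on logits keep the optimiser away from overflow. Initialisation
spreads step means over quantiles of the positive steps; subsequent
starts apply seeded log-normal jitter (default 25 starts; recovery tests
use fewer since well-separated states converge from almost anywhere).
The best start wins; states are then ordered by ascending mean step
length so that state 1 = resting, 2 = slow, 3 = fast. Within equal-length
batches series are sorted by track id before stacking, making the fit
invariant to input order. Given a seed the whole procedure is
deterministic. The initial state distribution is a free simplex; tracks
are short, so tying it to the stationary distribution is left as an
option.

Viterbi decoding breaks ties toward the lower state index. The
state-conditional deviation rate of grid cell i is (original sub-path
length within the cell − straight-line step length) / (grid interval in
minutes); the sub-path length is read off the cumulative arc length of
the original polyline, which is piecewise linear in time because speed is
constant within a leg. Rates are pooled across tracks and box-summarised
per decoded state.

## Synthetic cohort

The generator emulates a field campaign of 2 h foot-follows: a 1 Hz
latent correlated random walk with three movement states switched by a
Markov chain (geometric dwells — the memoryless choice consistent with an
HMM fit), per-second speed drawn from a gamma around the state mean, and
heading increments von Mises(0, κ_state). Defaults: resting 0 m/s (dwell
420 s), slow 0.25 m/s with κ = 2 (dwell 240 s), fast 0.85 m/s with κ = 60
(dwell 240 s); four subjects with speed multipliers (1.0, 0.7, 1.3,
0.85). These values were calibrated once, at design time, so that the
cohort reproduces the scale of real follow data: inter-fix intervals of
mean 18.8 s / SD ~10 s / max 60 s (the truncated-normal cadence location
is root-found so the realised mean equals the configured one — naive
truncation at [1, 60] would inflate it to ~20 s), per-leg displacements
averaging ~5 m, 2 h distances of roughly 0.4–4 km with median ~1.7 km,
and an inter-subject distance spread detectable by Kruskal–Wallis at the
magnitude seen in comparable field data (H ≈ 10–15 at N = 47). Fixes are
exact latent positions: the quasi-continuous track is treated as ground
truth, so GPS noise is off by default (a Gaussian jitter option exists
for robustness experiments). Per-track seeds are spawned from the master
seed via `SeedSequence.spawn`, so cohorts are bit-reproducible and tracks
independent.

What the generator does **not** emulate: goal-directed travel. A CRW has
no large-scale persistence, so its 2 h paths are more space-filling than
real foraging routes, and deviations at long intervals (≥ 30 min) are
substantially larger than field values. Passing tests on synthetic
cohorts therefore establish correctness of the machinery (geometry,
likelihoods, recovery of known parameters, orderings), not the absolute
bias magnitudes of any particular species; absolute correction curves
must come from real reference tracks. There is also no habitat structure,
no sleeping-site anchoring and no diurnal strategy switching.

## Problem sizes and runtime choices

Recovery simulations use the cohort sizes the analysis targets: 47 tracks
of 9 intervals for the curve model (100 replicates) and 47 series of 24
five-minute steps for the HMM (20 replicates, 3 optimisation starts —
sufficient for well-separated states). Enumeration oracles run at T ≤ 8,
where 3^T is exhaustive but fast. The end-to-end pipeline example uses
smaller cohorts purely for brevity of the narrative scripts.

## Known limitations

- The curve-model band omits variance-parameter uncertainty (delta method
  on fixed effects only); at ~400 observations this is minor but not zero.
- A Bayesian backend (weakly-informative priors, MCMC) would slot behind
  the same `fit_curve` interface but is not implemented; maximum marginal
  likelihood covers the reported surfaces.
- No distance-regular re-discretisation (grids are temporal), no spline
  interpolation, no GPS error smoothing.
- Transition probabilities carry no covariates, and the number of states
  is fixed at three by design.
- Pipeline reports are CSV/JSON plus optional PNG plots; there is no HTML
  report.
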