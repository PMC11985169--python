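# Methods

This note documents the statistical model, the simulation engine, the
synthetic study system the package is validated on, and the numerical and
design choices a maintainer would want to know about.

## Presence–background maximum entropy

The model treats the landscape as a finite set of cells represented by a
background sample and estimates a Gibbs density
`q(x) = exp(λ·f(x)) / Z` whose feature expectations match the presence
data. Fitting minimizes the regularized presence log-loss

    J(λ) = −mean_pres[η(x)] + log Σ_bg exp(η(x)) + Σ_j β_j|λ_j|,  η = λ·f.

This is convex; the optimizer is cyclic coordinate-wise proximal Newton
descent. Each coordinate takes a soft-thresholded Newton step
`λ_j ← ST(λ_j − g_j/h_j, β_j/h_j)` with `g_j, h_j` the gradient and
curvature of the smooth part under the current model distribution, the
step capped at 2.0 and backtracked (halved up to six times) until the
penalized objective does not increase. A sweep visits every feature;
convergence is declared when a full sweep improves the objective by less
than 1e−5 (`tol`), with a 500-sweep cap (`max_iter`) — hitting the cap
raises a warning and still returns the model, flagged via `converged`.
Because the updates are soft-thresholded, unhelpful features stay exactly
zero, which is what makes the AICc parameter count meaningful.

Objective-improvement credit is accumulated per source variable during
the fit (product features split credit half/half) and normalized to the
percent-contribution table, mirroring how the reference implementation
attributes gain to variables during its sequential fit.

**Features.** Variables are rescaled to [0, 1] by their training-background
range; linear, quadratic and pairwise-product features are polynomials of
the scaled value, forward/reverse hinges and step thresholds sit at
`n_knots` equally spaced background quantiles (default 50, as in the
reference implementation; the tests and the pipeline default to 8–10 to
keep desk-scale cost down — a resolution, not a statistical, parameter).
Clamping pins scaled values into [0, 1] at prediction time so projection
onto novel climates cannot extrapolate a polynomial; with `clamp=False`
linear/quadratic/product features extrapolate linearly while hinges and
thresholds saturate by construction.

**Regularization.** `β_j = rm × base(class, m) × max(sd_j, 1e−3) / √m`,
where `m` is the presence count, `sd_j` the presence standard deviation of
the feature, and `base` the published per-class default tables
(linear/quadratic/product 1.0→0.05 as m grows 0→100; hinge 0.5;
threshold 2.0→1.0; categorical 0.65→0.25), linearly interpolated. The
regularization multiplier `rm` scales every width.

**Normalization convention.** Presence rows are appended to the background
for the normalization constant, the standard presence–background
convention; it guarantees every presence has positive density on small
synthetic grids. Raw scores over this training set sum to exactly 1 (a
unit-tested invariant). The logistic output is `e^H·q/(1 + e^H·q)` with
`H` the model entropy over the training background — the τ = 0.5
calibration that the "logistic" output format of the reference
implementation fixes.

**Evaluation.** AUC is the Mann–Whitney rank statistic of presence vs
background scores (ties averaged). OR10 applies the 10th percentile of
*training*-presence logistic scores as an omission threshold to test
presences. AICc uses the raw-density log-likelihood at presences with
`k` = nonzero weights; records with `n − k − 1 ≤ 0` carry an undefined
flag and are excluded from model selection. Both replicate designs the
workflow reports are implemented: k-fold cross-validation (default, one
shared seeded fold assignment across all tuning candidates) and a single
75/25 subsample (used by the acceptance script's recovery check).

## Model selection grid

`default_grid()` enumerates rm = 0.1…4.0 by exact tenths (integer
fractions, so no floating-point drift) × the six feature-class sets
L, LQ, H, LQH, LQHP, LQHPT — 240 candidates. Selection is argmin ΔAICc
with ties resolved by lower mean OR10, then higher mean test AUC, then
smaller rm. `improvement_report` expresses optimized-vs-default changes
as percentages of the default ((AUC_opt−AUC_def)/AUC_def×100 and
(OR_def−OR_opt)/OR_def×100), rounded to two decimals.

## Occurrence thinning

Two passes, both order-dependent with first-seen-wins tie-breaking (the
reference tools are order-dependent and do not document their order, so
determinism is the only reproducible choice): (1) one record per cell of
a 5×5-km grid anchored at (−180°, −90°), cells laid out in local
equirectangular kilometres (east–west distances scaled by cos latitude);
(2) a greedy pass keeping a record iff its haversine distance to every
previously kept record exceeds the 5-km buffer. Geodesic distances use a
spherical Earth of radius 6371.0088 km throughout the package — at 5-km
thresholds the ellipsoidal correction is ~0.1%, far below a cell width.
Whether the original buffer pass used geodesic or planar distance is not
documented; geodesic is the conservative choice and is exercised by the
synthetic grids' real longitude/latitude placement.

## Predictor screening

Pearson correlations are computed at the background sample points (the
same sample the model uses), not over all raster cells — matching the
scale of the inference and bounding cost. Zero-variance layers are
flagged and excluded from correlation rather than reported as spurious
r-values. Retention: variables with zero model contribution are dropped
first; then pairs with |r| ≥ 0.7 are resolved greedily in decreasing |r|
(ties alphabetical), keeping the higher-contribution member. The
workflow's "retain > 10% contribution" phrasing is incompatible with its
own final 25-variable set (mostly < 1% contributions), so the
contribution floor is exposed as `min_contribution` defaulting to 0 — the
only reading consistent with that final set.

## Classification, change and centroids

Right-closed bins: unsuitable ≤ MTSPS < general ≤ 0.4 < moderate ≤ 0.6 <
high, exactly the inequality chain the workflow states. MTSPS maximizes
test sensitivity (score strictly above the cut) plus specificity
(background at or below it) over all observed scores, ties to the lowest
cut. On strong synthetic signals MTSPS can exceed 0.4; the pipeline then
caps the class cut just below 0.4 with a warning and records both values,
since the four-class scheme presumes the threshold below its first fixed
bound. Cell areas are closed-form spherical quads, so per-class areas and
area-weighted centroids are exact on the sphere; change summaries expose
their percentage denominator (`reference_area_km2`, default the baseline
suitable area) because printed change-rate tables rarely document theirs.

## Dispersal automaton

Synchronous update: each dispersal event computes, for every empty
suitable non-barrier cell,

    P_col = [1 − Π_i (1 − P_Disp(d_i)·P_Prop(age_i))] × P_Inv

over occupied sources within the kernel radius; a uniform draw then
colonizes. The bracketing — invasibility multiplying the bracket, not
inside the product — is the reading under which `P_Inv` acts as a
property of the target cell, which is how the source model describes it.
Distances are Euclidean in cell units rounded half-up to integer rings
(the kernel is indexed by ring; diagonal neighbours land in ring 1).
Newly colonized cells have age 0 and cannot seed until after the next age
increment; initial cells start at full maturity. The default propagule
ramp (1.0,) makes sources fully productive one step after colonization —
the maturity machinery is configurable but no ages are published for the
study species. Invasibility is binary by default (habitat ≥ threshold,
the behaviour the fixed 0–1000 threshold of 118 = MTSPS×1000 implies),
with `continuous` (habitat/1000) retained as an option.

Barrier semantics: barrier cells are never colonizable in either mode;
*strong* barriers additionally remove any source whose straight
source–target line crosses a barrier cell (computed once per simulation,
since barriers are static), *weak* barriers are transparent to transit.
This makes strong ⊆ weak colonization, a property the tests check under
common random numbers.

Runs follow the published schedule: per environment-change period
(default 2, e.g. 2050s and 2070s), swap in the period's habitat map,
decolonize cells that fell below threshold, then run 20 dispersal steps;
10 independent replicates by default, with per-replicate seeds spawned
deterministically from the config seed and logged. Headline summaries
count a cell as colonized when it colonizes in > 50% of replicates;
per-cell frequencies are always emitted. `unlimited_dispersal` is the
climate-envelope null model (every suitable cell reachable) and equals
the automaton exactly when the kernel is all-ones with radius at least
the grid diameter — an equivalence the tests verify.

## Synthetic study system

The generator emulates the structure the real workflow consumes:

* smooth correlated environmental surfaces — white noise convolved with a
  Gaussian kernel of the stated correlation length (default 20 cells on a
  100×100 grid of 5-km cells placed at 105°E, 25°N), standardized, plus a
  weak north–south gradient;
* a deliberately collinear pair (env_1/env_2 share a latent field,
  |r| ≈ 0.96) to exercise the screening stage, and a strictly
  non-negative bounded layer (`hfp`) emulating a human-footprint index;
* presences sampled without replacement (one per cell, matching the
  one-point-per-grid thinning endpoint) with probability proportional to
  a known logistic suitability;
* "future" stacks as additive drifts of named layers, and clumped binary
  barrier masks from a thresholded smooth field (correlation length a
  quarter of the climate layers', so patches resemble land-use blocks,
  not speckle; the barrier fraction is met within ±2% on grids ≥100×100).

The default truth is logistic(3·env_1 − 2·env_3 − 5): two effects of 3
and 2 landscape standard deviations on *independent* layers, and an
intercept making suitable habitat ≈ 9% of the landscape. The intercept
matters: sampling presences proportionally to a suitability field that
covers half the landscape caps the achievable AUC near 0.7 regardless of
model quality (the ranking ceiling of the true surface itself), whereas
the rare-species regime — the regime presence-background SDMs are
actually used in, and the right one for an endangered relict conifer —
gives the true surface a ceiling near 0.87, which fitted models approach
(held-out AUC 0.80–0.89 across seeds at n = 200).

What the generator does **not** emulate: real bioclimatic covariance
structure, categorical soil classes, sampling bias, spatial
autocorrelation between presences beyond what the smooth suitability
induces, and observation error. Passing tests therefore demonstrate the
*correctness of the machinery* (estimation, bookkeeping, simulation), not
field-data performance.

## Problem sizes

The test suite and acceptance script run on deliberately modest sizes
chosen as the smallest at which each property is statistically decisive:
60×60–100×100 grids, 80–200 presences, 600–4000 background cells, 4–10
hinge knots, reduced tuning grids (the full 240-candidate grid is
enumerated and bookkeeping-tested, not fitted), and 10,000 single-step
Monte-Carlo replicates on a 5×5 automaton grid (binomial SE ≈ 0.5% at
p = 0.5, giving 3σ bands tight enough to catch a mis-indexed kernel
ring).

## Known limitations

* No bias-file (sampling-effort) support; no MESS/extrapolation surfaces.
* AICc on presence raw scores follows the ENMeval convention; it is a
  ranking device, not an absolute goodness-of-fit measure.
* The coordinate-descent contribution ledger depends on sweep order (as
  it does in the reference implementation); contributions are
  interpretable comparatively, not as variance decompositions.
* Strong-barrier transit blocking uses a rasterized line-of-sight; very
  elongated kernels on coarse grids can let propagules "corner-cut" a
  diagonal barrier of single-cell width.
* The spherical-Earth areas and distances are exact for the sphere, not
  the ellipsoid (~0.1–0.3% relative error) — irrelevant at the reported
  precision but documented for completeness.
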