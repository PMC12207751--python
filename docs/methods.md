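# Methods

`petreldsm` implements a density-surface-modelling pipeline for aerial
strip-transect surveys of a small pelagic seabird (the European
storm-petrel, *Hydrobates pelagicus*, is the motivating species): gridded
counts with survey-effort offsets, engineered environmental covariates, a
negative-binomial penalized-spline habitat model with detectability
terms, and a bootstrapped total-abundance estimate. Because the real
survey and remote-sensing inputs are large external datasets, the
package carries a synthetic-survey generator with fully known ground
truth; every statistical claim the test suite makes is a recovery or
calibration statement against that truth.

## The count model

Counts `y_i` of birds per 4 × 4 km grid cell and survey pass are modelled
as negative binomial (NB2, `Var = mu + mu^2/theta`) with a log link:

    log mu_i = log a_i + beta_0 + f_xy(x_i, y_i) + sum_k f_k(z_ik)
               + g_{alt(i)}(seastate_i) + delta * 1[altitude_i = high] + b_year

* `a_i` is the on-effort strip area inside the cell (km²); its log enters
  as an offset, so the linear predictor models density.
* `f_xy` is a bivariate thin-plate regression spline of the planar
  coordinates (default basis rank 30) absorbing residual spatial
  autocorrelation.
* each habitat covariate `z_k` (distance to coast, distance to the 500 m
  isobath, depth, slope, chl-a, SST, SSS, their gradient magnitudes,
  colony proximity score, Julian day) gets a univariate thin-plate
  regression spline with at most five knots and a *double* shrinkage
  penalty (below), so uninformative terms can leave the model entirely.
* `g_alt` is a factor-smooth interaction: one centred smooth of mean
  Beaufort sea state per survey-altitude class, capturing
  detectability decline in rougher seas that may differ by altitude.
  Because each of those smooths is centred, the mean detectability
  difference between altitudes is carried by the parametric `delta`
  (altitude entered with "low" as the reference level: low-altitude,
  calm-sea survey is the best-detection regime).
* `b_year` is an i.i.d. Gaussian random effect (ridge-penalized
  indicators) in the distribution model, a fixed factor in the
  detectability model; the distribution model drops it and refits when
  its Wald p ≥ 0.05.

### Spline engine

Bases are eigen-truncated thin-plate regression splines: the radial-basis
matrix at (a deterministic, evenly-spaced subset of) the unique covariate
values is eigendecomposed, the `k` leading eigenvectors retained, and the
polynomial-orthogonality constraint absorbed. Each smooth is centred
(sum-to-zero over the training rows), so a rank-`k` basis contributes
`k − 1` columns. The wiggliness penalty is the truncated thin-plate
penalty projected to its positive part; a second penalty spans the exact
orthogonal complement within the term (its null space, including the
linear/planar directions), so driving both smoothing parameters to
infinity removes the term completely ("shrinkage to zero"). Because the
two penalties of a term are mutually orthogonal and terms occupy disjoint
columns, the log-pseudo-determinant of the total penalty — needed by the
REML criterion — is available in closed form, which keeps
smoothing-parameter optimisation cheap.

Fitting alternates (performance iteration):

1. penalized IRLS for the coefficients at fixed smoothing parameters and
   `theta` (Fisher weights `mu/(1 + mu/theta)`, step-halving on the
   penalized deviance, convergence at 1e-10 relative change *and* 1e-8
   relative coefficient change, max 200 iterations);
2. golden-section search for `theta` on the exact NB log-likelihood at
   the current fitted means (bounds 0.02–5·10⁷ on the log scale);
3. L-BFGS-B on the log smoothing parameters (bounds ±15) of a
   working-model REML criterion
   `D_w/(2γ) + βᵀSβ/2 + ½log|XᵀWX/γ + S| − ½log|S|₊`,
   where `γ = 1.2` divides the data-information term — the same
   smoother-fits-preferred effect as inflating the degrees-of-freedom
   cost. A GCV criterion (`n·D_w/(n − γ·edf)²`) is available as a switch.

The loop ends when the log smoothing parameters move < 0.02 and `theta`
is stable. Effective degrees of freedom per term are the trace of the
relevant block of `(XᵀWX + S)⁻¹XᵀWX`; AIC is `−2ℓ + 2·edf`; deviance
explained is `1 − D/D_null` with the null model an intercept-plus-offset
fit at the same `theta`. Per-term p-values are Wald-type chi-square
statistics on the Bayesian posterior covariance `(XᵀWX + S)⁻¹`, with the
test df floored at 1 so a fully-shrunk term cannot appear spuriously
significant. They are approximate, as such statistics always are for
penalized smooths.

On shared fixtures the engine reproduces mgcv's shrinkage-smoother fits
(fitted curves correlate > 0.98; predicted totals agree to three decimal
places across replicate datasets), matches a plain Poisson GLM at
`theta → ∞` to < 1e-4 in every coefficient, and honours the offset
contract (scaling all efforts by `c` shifts only the intercept, by
`−log c`).

### Model selection

Concurvity between terms is measured as the squared largest canonical
correlation between one term's centred basis columns and the span of the
others' ("worst" measure, in [0, 1]); pairs above 0.8 are grouped by
transitive closure. Structural terms — the spatial smooth, the sea-state
factor smooth, altitude, year — are always retained; within each
correlated group of habitat covariates every subset is fitted (≤ 2¹²)
and the lowest-AIC candidate wins, ties (< 1e-6) broken toward fewer
total edf. All candidates, the full set included, are fitted under one
warm-started protocol (smoothing parameters and `theta` started from a
preliminary full fit, capped outer iterations) so the comparison is
symmetric. Smooth spatial covariate fields make these groups large —
spatially smooth variables inevitably share span with the coordinate
spline — which is why the exhaustive search is warm-started rather than
cold.

A caution from our replicate experiments: because a shrunk extra term
costs almost nothing in AIC (2·edf → 0), strict lowest-AIC keeps a noisy
duplicate of a real covariate in a substantial minority of replicates.
The reliable signatures of the true covariate are that it is always
retained and its edf dominates the duplicate's.

## Effort, counts and covariates

The survey strip is the trackline buffered 0.2 km each side (flat caps,
mitred joins); off-effort pieces are excluded, overlapping strips within
a pass are unioned before clipping, and the clipped area per cell is the
effort `a_i`. A pass is one transect flight; repeat coverage yields
separate rows. Cells follow the half-open convention (a boundary point
belongs to the +x/+y cell). Mean sea state per (cell, pass) is
length-weighted along the in-cell trackline. Counts are sums of group
sizes; a sighting whose (cell, pass) has no surveyed strip is kept with
zero effort and a warning, so counts are conserved exactly. The
detectability study uses only cells surveyed at both altitudes, so the
altitude effect is not confounded with the coastal/offshore gradient.

Covariates per sea-cell centre: Euclidean distance to the land/sea
boundary and to the 500 m depth contour (both as cell-edge midpoint
sets); depth clamped ≤ 0 where a centre sits over land artefacts; slope
and field-gradient magnitudes by Horn's 3 × 3 method (edge cells by
replicate padding; missing cells filled from the nearest valid neighbour
before differencing and re-masked after, so coastal cells keep finite
gradients); inverse-distance-weighted appending (power 2, exact-hit
rule, optional search radius); 8-day temporal windows `[8k+1, 8k+8]`
(day 195 → days 193–200), with daily salinity averaged over the window.

The colony proximity score is `Σ_c pairs_c / max(d_ic, d_min)²` with
`d_ic` the least-cost over-sea path length from the cell centre to the
colony's nearest sea cell on the 8-connected cell graph (orthogonal step
= cell size, diagonal = √2 × cell size; octile error vs. true Euclidean
≤ 8%) and `d_min` = half a cell — the clamp keeps the colony's own cell
finite. Colonies unreachable from an enclosed basin contribute zero
there, with a warning.

Skewed covariates (|sample skewness| > 1 among a configurable candidate
list) are Box-Cox transformed; λ maximises the profile log-likelihood,
scanned on a 0.01 grid over [−2, 2] and refined by golden section, with
an automatic shift `1 − min(x)` when needed. λ and shift are persisted
and re-applied verbatim on the prediction grid — never re-estimated.

## Abundance, uncertainty, validation

Predictions use the selected model at standardized best-detection
conditions — median surveyed Julian day, Beaufort sea state 0, low
altitude — with a full-cell offset `log(16 km²)`, so each cell's
prediction is density × area; the total is rounded once, at the end.
Per-cell CV is the delta-method `SE(mu)/mu`, which on the log link equals
the link-scale standard error.

The 95% CI is a winsorised percentile bootstrap: the highest counts are
capped at the 97.5th percentile *of the positive counts* (surveyed cells
are mostly zeros; a zero-inclusive quantile would sit at 1–3 birds and
truncate ordinary sightings rather than outliers, dragging every
bootstrap total down — measured cost: CI coverage of the true total
drops from ~95% to ~75%); surveyed rows are resampled with replacement;
the selected model structure is refitted per replicate — the spline
bases and centring constraints are part of the structure and are reused,
smoothing parameters are re-optimised from a warm start, `theta` is held
at the point fit's estimate (re-profiling it changed trial intervals by
< 1% at three times the cost); the CI is the 2.5th/97.5th percentiles of
the replicate totals. Replicates that fail to converge are dropped and
counted; > 20% failures is an error. The generic `winsorise` operation
itself uses the plain zero-inclusive interpolated quantile. The point
estimate uses raw (unwinsorised) counts. A cheaper parametric mode
(coefficients drawn from the posterior) is available as a switch and
agrees with the refit mode to ~25% in interval midpoint on trial data.

Validation follows an 80/20 × 100 design: disjoint, exhaustive random
splits; the model structure is refitted on each training set and scored
by total predicted versus observed count on the held-out rows; the
report carries the share of iterations within ±5% and ±10% and the
signed mean error (negative = underestimation, the direction
density-surface smoothing bias pushes).

## The synthetic world

`synthetic.py` generates: Gaussian random fields by Gaussian-filtered
white noise on a torus (filter scale σ = ℓ/√2 gives covariance
`exp(−r²/2ℓ²)`; the sample is normalised to its empirical variance, so
`sd` is exact per realisation and `sd = 0` yields a constant field);
bathymetry deepening with distance from land plus a noise field, clamped
≤ 0 at sea; an elliptical main island with circular islets, rasterised at
cell resolution; colonies on coastal land cells with Dirichlet-split
breeding pairs; a log-linear true density surface
`log λ = c + Σ f_k(z_k)` with closed-form partial effects (coastal
avoidance peaking 20–40 km offshore, preference for water deeper than
~160 m, a mild SST trend), the intercept calibrated so the default
450,000 km² world holds ~150,000 birds (mean density ~0.33 birds/km²);
east-west strip transects perpendicular to the coast (broad lines at
10 km spacing flown "high", a fine block at two-nautical-mile spacing
flown "low"), each carrying a Julian day, a year and a piecewise-constant
sea-state sequence in 40 km blocks with ≥ 95% of mass at Beaufort ≤ 3
and a 3% off-effort rate per block. Latent birds per cell-strip
intersection are NB with mean λ × area and size `theta = 2`; they are
partitioned into groups (80.5% singletons, 10.7% pairs, geometric tail —
matching observed storm-petrel sighting composition) and each group is
retained with probability
`min(1, exp(δ_alt·1[high] + β_ss(alt)·seastate))`, equal to 1 at sea
state 0 and low altitude; defaults `δ_alt = log 0.5`,
`β_ss = −0.20 (high) / −0.10 (low)` per Beaufort class.

What the generator does *not* emulate: real coastal geometry and
bathymetry; temporal dynamics within a season (fields are static, so
Julian day is pure noise in the synthetic world); responsive movement of
birds to the aircraft; availability bias (birds resting on the water);
observer-specific error. Passing tests therefore demonstrate that the
pipeline recovers what it models — density given detectability structure
— not that those unmodelled biases are absent in real data. One known
generator artefact: at sparse densities the latent count per
cell-strip intersection is often 1, which truncates sampled group sizes
and raises the realised singleton share above the nominal 80.5%.

## Problem sizes and study designs

The replicate studies in `studies.py` (used by the tests and the
acceptance script) run at desk scale: smooth recovery and shrinkage at
n = 2000 cells with mean count ~0.6 and θ = 2 (the sparse-count regime
aerial storm-petrel surveys live in); detectability power/type-I at 800
dual-surveyed cells × 2 passes, 25 and 50 replicates; abundance recovery
over 25 worlds of ~3400 sea cells with 2000 surveyed; bootstrap coverage
over 100 worlds of 600 cells at B = 200; validation at n = 2000 with 100
splits. The analysis drivers run a quarter-scale world (~113,000 km²,
~6,600 sea cells, ~13,000 km of trackline) end-to-end; the full-scale
default world is exercised by the generator tests.

## Known limitations

* The REML criterion is the Gaussian working-model (performance
  iteration) approximation, not full Laplace REML; fitted curves match
  mgcv closely, but shrinkage of genuinely null terms has a slightly
  heavier edf tail. Under either implementation, REML leaves a null
  term's edf between 0.5 and 1 in roughly a sixth of sparse-count
  replicates — full removal of null terms is soft, not guaranteed.
* Wald p-values on smooth terms are approximate; no simulation-based
  residual diagnostics are included.
* Land-avoiding distances use the octile metric on the cell graph, an
  upper-bounded (≤ 8%) overestimate of true over-water distance.
* The bootstrap resamples cell-pass rows independently, ignoring
  residual spatial correlation between nearby cells; with a spatial
  smooth in the model this is the standard, but optimistic, choice.
* Random-effect prediction at unobserved levels is not supported; the
  pipeline drops a non-significant year effect before prediction, and a
  retained year effect requires choosing a reference year.
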