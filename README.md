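# petreldsm

Density surface modelling of aerial strip-transect seabird surveys, built
around the survey design used for European storm-petrels (*Hydrobates
pelagicus*) — one of the smallest seabirds, hard to census at its cryptic
nocturnal colonies and imperfectly detected from the air. The package
takes raw transect and sighting records through to a gridded abundance
surface with uncertainty: strip-effort gridding, environmental covariate
engineering, a negative-binomial penalized-spline habitat model with
survey-detectability terms, and a winsorised-bootstrap total-abundance
estimate. A synthetic survey generator with fully known ground truth
makes every stage testable without external data.

## The model

Counts `y_i` of birds per 4 × 4 km cell and survey pass follow

    y_i ~ NB(mu_i, theta),
    log mu_i = log a_i + beta_0 + f_xy(x_i, y_i) + sum_k f_k(z_ik)
               + g_alt(i)(s_i) + delta * 1[altitude_i = high] + b_year,

with `a_i` the on-effort strip area in the cell (log offset), `f_xy` a
bivariate thin-plate spline of the coordinates, `f_k` shrinkage
thin-plate splines (max five knots, double penalty so a term can shrink
out of the model entirely) of habitat covariates — distance to coast,
distance to the 500 m isobath, depth, slope, chl-a, SST, SSS, their
gradients, a land-avoiding colony proximity score `sum_c pairs_c / d_c²`,
and Julian day — `g_alt` a per-altitude centred smooth of Beaufort sea
state, `delta` the parametric survey-altitude detectability effect, and
`b_year` a year random effect. Smoothing parameters are selected by a
REML-type criterion with complexity inflation `gamma = 1.2`; `theta` is
profiled by golden section; correlated covariates (concurvity > 0.8) are
resolved by exhaustive lowest-AIC subset search. Abundance is predicted
at standardized best-detection conditions (median Julian day, sea state
0, low altitude) with a full-cell offset, and its 95% CI comes from a
winsorised percentile bootstrap with per-replicate refits.

The spline engine is implemented in the package (`petreldsm.nbgam`) and
is cross-checked against mgcv in the test suite.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
quarter-scale synthetic world (~113,000 km², ~6,600 sea cells) defined in
`analysis/config.yaml`; each writes its tables under `results/`:

    cd analysis
    python 01_simulate_survey.py
    python 02_grid_effort.py
    python 03_covariates.py
    python 04_detectability.py
    python 05_distribution.py
    python 06_validate.py
    python 07_abundance.py

With the shipped configuration (seed 11) this prints, in order:

    world: 6582 sea cells; true total 75000 birds
    survey: 65 transects, 12841 km trackline (96.6% of effort at sea state <= 3)
    sightings: 1411 groups, 1570 individuals (91.4% singletons)
    ...
    dual-altitude subset: 494 rows over 226 cells surveyed at both altitudes
    ...
    altitude effect (high vs low): -0.930 on the log scale -> detection ratio 0.39, p = 8.6e-08
    ...
    50% of test predictions within 5% of observed; 82% within 10%
    ...
    total abundance: 66,629 (95% CI 50,859 - 79,933, B = 300)
    known true total: 75,000 -> estimate/truth = 0.888; CI covers truth: True

Reading those numbers: the generator thinned high-altitude detections by
`exp(-0.69) = 0.5` plus a sea-state penalty, and the fitted parametric
altitude term recovers a detection ratio of 0.39 against a truth of
~0.43 once the mean sea-state difference it absorbs is included — the
high-altitude broad-scale survey sees roughly half the birds. The final
abundance estimate sits 11% below the known total (density-surface
smoothing biases totals low, the same direction the validation split
flags), and the bootstrap interval covers the truth.

## Layout

    src/petreldsm/
      synthetic.py    world generator: fields, colonies, truth, transects, sightings
      gridding.py     grid, strip-effort areas, count aggregation, dual-altitude subset
      covariates.py   distances, gradients, IDW, 8-day windows, colony score, Box-Cox
      nbgam.py        the NB-GAM engine: bases, penalties, PIRLS + REML, prediction
      selection.py    concurvity screen, exhaustive AIC selection, the two studies
      abundance.py    prediction grid, totals, CV, winsorised bootstrap, validation
      studies.py      seeded replicate studies (power, recovery, coverage)
    analysis/         numbered drivers over the library (see worked example)
    tests/            pytest suite; test_acceptance.py holds the statistical checks
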