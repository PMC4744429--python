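# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Two-stage model

### Stage one: within-tract additive model

Within each tract, term birth weight (g) is modelled as
y_i ~ N(mu_i, sigma), mu_i = a0 + beta * x_i + sum_j s(x_ij) + sum_k f(x_ik),
optionally on a transformed outcome scale (identity by default; log and
box-cox(lambda) are available, with the log-Jacobian carried into the
deviance so DIC comparisons across transforms are on the original scale).

- **Pollutant slope prior.** beta (g per ppb) carries an elicited normal
  prior: mean = sample-size-weighted mean of published effects, sd =
  weighted population-convention sd (both per 10 ppb, divided by 10 for the
  model scale). The population (÷Σn) convention is stable for as few as two
  studies. For a pollutant with sparse or conflicting evidence the prior is
  a weakly informative N(0, 1) per ppb ("weak_normal"); the per-ppb default
  is a choice — the alternative per-10-ppb reading is obtained by passing
  the scale note and rescaling.
- **Confounder smooths.** Cubic B-splines, 10 interior knots at covariate
  quantiles, second-order random-walk penalty with IG(0.001, 0.001)
  smoothing variance. Spline columns are centred over the observed values,
  so each fitted smooth sums to zero and the intercept absorbs the level.
  A constant covariate is dropped with a warning (its basis is degenerate).
- **Factors.** Dummy coding against the most frequent level per tract
  (small tracts may not observe every level; the most frequent one always
  exists). A rank-deficient factor block is an error naming the factor; a
  single-level factor is dropped as carrying no contrast.
- **Sampler.** Blocked Gibbs: one joint multivariate-normal update for all
  coefficients (the exposure column is mean-centred, which leaves the slope
  untouched and decorrelates it from the intercept), IG updates for the
  smoothing variances and the residual variance (IG(0.001, 0.001), the
  convention of the structured-additive-regression tooling era this model
  descends from). Intercept and factor priors are N(0, 10^6), effectively
  flat after outcome centring. A known residual sd can be fixed
  (`sigma_fixed`), which makes the coefficient draws exact iid posterior
  samples and enables closed-form verification.
- **Diagnostics.** DIC = Dbar + pD with pD = Dbar − D(posterior means);
  PSRF of the slope across chains, with fits flagged (not discarded) above
  the 1.05 gate. The gate is deliberately looser than the ~1.01–1.03 values
  a well-mixed run attains.
- **Residual screen.** Per-tract Moran's I of posterior-mean residuals on
  symmetrised k-nearest-neighbour (k = 8) weights at residential
  coordinates; tracts with < 10 residuals are skipped with a warning. The
  reported fraction of tracts with p ≥ 0.05 is the evidence for omitting a
  within-tract spatial residual term — which this package, like the
  analysis it implements, does not fit.

### Stage two: between-tract structured additive model

The per-tract posterior slopes beta_hat (g per ppb) are treated as noisy
observations of a tract-level surface:
beta_hat_c ~ N(eta_c, V_c), eta_c = alpha0 + sum_j s(c_jc) + eps_c.

- **Measurement variances V.** V_c is the square of the stage-one posterior
  sd, treated as known — the classic two-stage plug-in. This is the central
  under-specification of the two-stage design: V is itself an estimate, and
  with informative slope priors it reflects prior as well as data
  precision. A scalar `v_inflation` is exposed for sensitivity analyses.
- **Smooths.** P-splines: cubic B-spline bases on 20 equidistant interior
  knots with a second-order random-walk penalty and IG(0.001, 0.001)
  smoothing variances. Each smooth is recentred to sum to zero over the
  observed tracts every sweep (the RW2 null space contains the constant,
  which would otherwise trade off against alpha0).
- **Spatial field.** Proper CAR with precision tau^-2 (D − rho W) on binary
  rook weights (shared boundary segment, not corner contact). rho has a
  uniform prior on its admissible interval (1/lambda_min, 1/lambda_max) of
  the normalised adjacency spectrum and is sampled by griddy Gibbs on a
  101-point grid, using eigenvalues precomputed once for the log-determinant.
  tau² is IG(0.001, 0.001).
- **Intercept and field sampled jointly.** alpha0 and the field phi are one
  Gaussian block. The proper CAR prior identifies the field's level, so the
  joint update both removes the strong Gibbs correlation between alpha0 and
  mean(phi) and propagates the field-level uncertainty into alpha0's
  credible interval. (Sweep-recentring phi into alpha0 — the common
  intrinsic-CAR identification device — is *not* used here: with a proper
  CAR it pushes the realised field mean into alpha0 without its
  uncertainty, and alpha0's intervals become anti-conservative.)
- **Reporting scale.** alpha0 is sampled per ppb and reported per 10 ppb;
  the reported draws are exactly 10× the internal ones.

### Stage-two summaries

- **Quartile contrast**: 10 · (s(q75) − s(q25)) per posterior draw, where
  q25/q75 are the covariate's quartiles across tracts; centring cancels in
  the difference. Units: g per 10 ppb.
- **Threshold detection**: the derivative of each smooth is computed
  analytically from the B-spline basis on a 201-point grid. A threshold
  onset exists when the pointwise 95 % band of the derivative excludes zero
  somewhere and the half-maximum region of the posterior-mean derivative
  does not span (≥ 95 % of) the whole domain — a constant derivative
  (linear smooth) therefore has no onset. The run is anchored at the grid
  point whose *credible lower-bound* magnitude is largest: boundary
  wiggles, which have large posterior-mean derivatives but wide bands,
  cannot anchor it. The reported interval is the central 95 % of the
  posterior distribution of the onset location — per draw, the point where
  the derivative magnitude last drops below half its value at the anchor.
  This replaces a single posterior-mean crossing (a one-grid-step bracket
  that understates onset uncertainty) with a genuine credible interval.
- **Variance decomposition**: across-tract variances of (i) the
  posterior-mean spatial field, (ii) the summed posterior-mean smooth
  contributions, and (iii) the residual beta_hat − posterior-mean eta,
  normalised to sum to one. The measurement variance V is deliberately
  excluded from the denominator: the shares describe the *modelled*
  between-tract variability, and the report says so.
- **P(effect < 0)**: Monte-Carlo fraction of negative eta draws per tract
  (≥ 100 draws required).

## Synthetic-data generator

The generator emulates the restricted inputs: a grid_side × grid_side
lattice of 2 km × 2 km square tracts (area 4 km², the study region's mean
tract area), tract covariates, a true slope decomposition, and individual
birth records.

- **Tract covariates** are transforms of standard-normal latent fields,
  optionally neighbour-averaged (two passes, re-standardised) so they carry
  the positive spatial autocorrelation real census covariates have.
  Percentage covariates map through a probit link into stated ranges;
  income is log-normal; freeway distance exponential. The ethnicity/
  education percentage columns are generated independently (they are not
  constrained to a simplex) — adequate for effect-modification testing,
  not for compositional analyses.
- **True slopes**: beta_true = alpha0 + centred smooth contributions +
  proper-CAR field drawn by Cholesky of the precision. Defaults:
  alpha0 = −1.47 g/ppb (−14.7 g per 10 ppb, the effect scale the model is
  designed to recover), a linear modifier on pct_drive_to_work (slope −3
  g/ppb per unit), a threshold modifier on pct_heavy_industry (knee at
  0.18, slope −10 g/ppb per unit beyond it), rho = 0.9, tau = 0.5 g/ppb.
  Smooth contributions are centred across tracts, so alpha0 is exactly the
  population-average slope.
- **Births**: 50–500 per tract (the lower bound mirrors the 50-birth tract
  floor used in cohort preparation); exposure log-normal matched to mean
  25.00 ppb / IQR 11.43 ppb; weight = baseline + beta_true · exposure +
  centred confounder contributions + N(0, 450 g). The 450 g residual sd is
  a conventional term-birth-weight spread — a knob, not an estimate. The
  baseline is derived so the expected weight equals 3393 g. Confounder
  effects (sex ≈ 60 g, gestation 50 g/week, inverted-U maternal age,
  ethnicity/education offsets of tens of grams) are centred simulation
  knobs of modest, documented magnitude; they are independent of exposure,
  so unadjusted slope estimates remain unbiased. Gestation is integer 37–45
  weeks. Exposure is drawn iid within tracts from the study-wide marginal —
  more within-tract exposure contrast than a real cohort has, hence
  stage-one slopes here are better identified than in the field.
- **What passing tests do not show**: the generator has no exposure
  measurement error, no residential mobility, no within-tract exposure
  clustering, no missing data, and no confounder–exposure correlation;
  recovery results on it validate the estimator's correctness, not its
  robustness to those real-data features.

## Cohort preparation

Birth rules (sequential, each record counted once, in order): multiples →
recorded defects → unknown defect status → outside the 37–45-week term
window. Tract rules (sequential): area > 50 km² → fewer than 50 births →
islands, with connectivity recomputed after earlier removals (removals can
create new islands; the alternative island-first order is exposed as
`island_before_area` for sensitivity) → Tukey outer-fence outliers
(Q1 − 3·IQR, Q3 + 3·IQR, linear-interpolation quantiles, pinned so fences
are bit-stable) on tract-mean birth weight and every supplied covariate,
union of flags. Adjacency is re-derived on the kept set. The tally is
conservative by construction (input = output + Σ rule counts) and
re-filtering the kept set removes nothing. Trimester windows default to
weeks 1–13, 14–26, 27–delivery (the dominant obstetric convention; the
boundaries are arguments). Block-to-tract covariate aggregation is
area-weighted.

## Prior–data balance

At within-tract sample sizes of a few hundred births, the elicited NO₂-style
prior (sd ≈ 0.4 g/ppb after rescaling) is strong relative to a single
tract's likelihood (slope s.e. ≈ 2–3 g/ppb), so stage-one posteriors pool
heavily toward the literature consensus; a weakly informative prior leaves
the slopes data-driven and preserves the between-tract variability stage
two explains. Both regimes are legitimate uses of the method — the
acceptance script reports both tracks, and parameter-recovery checks use
the weak prior so that coverage reflects the estimator rather than the
prior.

## Problem sizes and MCMC defaults

Defaults are 9 chains × 4000 iterations, 2000 burn-in, thinning 2, PSRF
gate 1.05, for both stages. Tests and the acceptance script use 2–3 chains
of a few hundred to a few thousand iterations on 5×5 to 15×15 lattices —
sizes chosen so the full suite runs in minutes while leaving Monte-Carlo
error well inside the tolerances being checked; conjugate structure makes
the samplers' draws nearly uncorrelated, so short chains are adequate
there. All randomness flows through explicit seeds; per-tract and per-chain
seeds are derived with `numpy.random.SeedSequence` spawn keys, so results
are independent of execution order.

## Known limitations

- The within-tract spatial residual (variogram covariance) is screened for
  but never fitted, by design.
- Single-pollutant models only; NO₂/NOₓ-style exposures are strongly
  collinear and are analysed separately.
- The stage-two response is a plug-in estimate; full joint propagation of
  stage-one uncertainty (e.g. by sampling the two stages together) is out
  of scope.
- GeoJSON export is the only mapping output; no map rendering.
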