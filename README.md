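# airbw — spatially varying air-pollution effects on term birth weight

`airbw` implements a two-stage Bayesian hierarchical pipeline for asking
*where* an air pollutant harms birth outcomes more, and *which
neighbourhood factors* modify that harm. It is written for environmental
epidemiologists working with individual birth records, tract-level census /
land-use covariates, and modelled exposure surfaces (NO₂- or NOₓ-style
pollutants in ppb). Because birth registries are restricted, the package
ships a synthetic-cohort generator with the exact statistical structure the
model assumes, so every stage is runnable and testable out of the box.

## The model

**Stage one** (within each census tract *c*): a Bayesian additive model for
individual term birth weight

&nbsp;&nbsp;&nbsp;&nbsp;yᵢ꜀ ~ N(μᵢ꜀, σ꜀),&nbsp;&nbsp;
μᵢ꜀ = a₀꜀ + x꜀ᵖ β꜀ᵖ + Σⱼ s꜀(xⱼ꜀) + Σₖ f꜀(xₖ꜀),

with a literature-elicited normal prior on the pollutant slope β꜀ᵖ
(g per ppb): the prior mean and sd are the sample-size-weighted mean and sd
of published effects (g per 10 ppb, rescaled). Continuous confounders enter
through cubic B-spline smooths with random-walk penalties; categorical
confounders as factor effects. All full conditionals are conjugate, so the
model is fit by a blocked Gibbs sampler; DIC ranks model variants and
within-tract residuals are screened with Moran's I to justify omitting a
within-tract spatial term.

**Stage two** (across tracts): the estimated slopes β̂꜀, with their
posterior variances V꜀ treated as known, follow a structured additive model

&nbsp;&nbsp;&nbsp;&nbsp;β̂꜀ ~ N(η꜀, V꜀),&nbsp;&nbsp;
η꜀ = α₀ + Σⱼ s(cⱼ꜀) + ε꜀,&nbsp;&nbsp;
ε ~ N(0, τ² (D − ρW)⁻¹),

where each s(·) is a P-spline over a tract covariate (income, ethnicity
percentages, commute patterns, land use, NDVI, distance to freeway), and ε
is a proper conditional-autoregressive (CAR) field on binary rook adjacency
W with neighbour-count diagonal D. α₀ is the population-average pollutant
effect, reported in g per 10 ppb. Nine MCMC chains (by default) are pooled
after burn-in and convergence is diagnosed with the Gelman–Rubin PSRF.
Stage-two outputs include posterior smooth curves with credible bands,
Q1→Q4 quartile contrasts per covariate, threshold-onset intervals of the
smooths, a spatial/smooth/residual variance decomposition, and per-tract
P(effect < 0) maps.

## Worked example

Stage two on a 15×15 synthetic lattice with a known truth
(α₀ = −1.47 g/ppb, one linear and one threshold effect-modifier, CAR field;
see `examples/04_tract_level_model.py`):

```text
alpha0 -15.5 [-17.5, -13.8] g per 10 ppb   (truth -14.7)
CAR: rho 0.91, tau 0.42   max PSRF 1.004
pct_drive_to_work      Q1->Q4 contrast  -7.60 [-9.25, -5.99] g/10ppb; threshold onset in [0.354, 0.634]
pct_heavy_industry     Q1->Q4 contrast  -0.73 [-2.41, 1.04] g/10ppb; threshold onset in [0.128, 0.194]
variance shares: {'spatial': 0.13, 'smooth': 0.72, 'residual': 0.15}
tracts with P(adverse) > 0.95: 224 of 225
```

The 95 % credible interval for α₀ covers the generating value; the
drive-to-work contrast says top-quartile commuter tracts lose ≈7.6 g more
birth weight per 10 ppb than bottom-quartile tracts; the heavy-industry
threshold interval brackets the generating knee at 18 % land share; and the
CAR field recovers the generating dependence (ρ = 0.9, τ = 0.5).

Other examples: `01_elicit_prior.py` (literature pooling),
`02_simulate_cohort.py` (generator and its truth decomposition),
`03_single_tract_fit.py` (stage one on one tract),
`05_full_pipeline.py` (end-to-end run with report).

## Command line

The same pipeline is available as a thin CLI:

```bash
airbw run-all --config config.yaml --seed 1 --outdir runs/demo
airbw simulate ... ; airbw prep ... ; airbw stage1 ... ; airbw stage2 ... ; airbw report ...
```

Each stage reads and writes plain files (CSV / GeoJSON / JSON) under the
output directory, so stages are resumable and reruns with the same config
and seed reproduce identical file digests (recorded in `manifest.json`).

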