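"""Elicit the pollutant-slope prior from a literature effect-size table.

Each published study contributes its effect on term birth weight (grams per
10 ppb of NO2-like exposure) weighted by its sample size; the pooled mean
and spread become a normal prior for the per-tract slope.
"""

from airbw import pipeline, priors

studies = priors.read_literature_csv(pipeline.default_literature_table())
print(f"{len(studies)} studies included (one meta-analysis row excluded "
      f"via the include column)")

prior = priors.weighted_normal_prior(studies)
print(f"elicited prior: N({prior.mean:.2f}, {prior.sd:.2f}^2) g per 10 ppb")

model_prior = priors.prior_to_model_scale(prior, 10.0)
print(f"on the model (per-ppb) scale: N({model_prior.mean:.3f}, "
      f"{model_prior.sd:.3f}^2) g per ppb")

weak = priors.noninformative_prior()
print(f"weakly informative alternative (mixed-evidence pollutant): "
      f"N({weak.mean:.0f}, {weak.sd:.0f}^2) g per ppb")

# The prior mean is the literature consensus effect; its sd encodes
# between-study heterogeneity and controls how strongly each tract's fit
# is pulled toward that consensus.
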