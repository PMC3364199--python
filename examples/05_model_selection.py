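"""Bayesian covariate selection with inclusion indicators.

Each candidate covariate carries a latent Bernoulli(0.5) inclusion
indicator applied at the community level; posterior indicator
frequencies give covariate inclusion probabilities and posterior model
probabilities over the whole candidate set.
"""

import numpy as np

from commoccu import (
    CommunityModelSpec,
    GeneratorConfig,
    McmcConfig,
    candidate_set_size,
    generate_dataset,
    inclusion_probabilities,
    posterior_model_table,
    predict_marginal_occurrence,
    render_model_table,
    run_mcmc,
)

cfg = GeneratorConfig(
    n_species=5, n_sites=80, n_arrays=12,
    occ_covariates=("patrol", "river", "small_prey"), det_covariates=("road", "team"),
    mu_alpha=(0.0, 0.0, 1.2), sigma_alpha=(0.25, 0.8, 0.4),
    mu_beta=(0.4, -0.9), sigma_beta=(0.3, 0.3),
)
data, covariates, truth = generate_dataset(cfg, seed=9)

spec = CommunityModelSpec(occ_covariates=list(cfg.occ_covariates),
                          det_covariates=list(cfg.det_covariates))
print(f"candidate set: {candidate_set_size(spec)} models "
      f"(2^{len(spec.occ_covariates) + len(spec.det_covariates)})")

mcmc = McmcConfig(n_chains=3, n_iter=4000, n_burnin=800, thin=4, seed=9)
samples = run_mcmc(data, covariates, spec, mcmc, selection=True)

print("\nposterior inclusion probabilities (prior was 0.5 each):")
print(inclusion_probabilities(samples).round(3).to_string())
table = render_model_table(posterior_model_table(samples), top=5)
print("\ntop-ranked models by posterior probability:")
print(table.to_string(index=False))

curve = predict_marginal_occurrence(
    samples, samples.species[0], "small_prey", np.linspace(-2, 2, 5)
)
print(f"\nmarginal occurrence of {samples.species[0]} vs standardized "
      "small-prey biomass (other covariates at their mean):")
print(curve.round(3).to_string(index=False))
print("\nA strong planted effect should appear with inclusion probability "
      "near 1 and dominate the top-ranked model formulas; null covariates "
      "hover near the 0.5 prior or drop out.")
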