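"""Fit the hierarchical multi-species occupancy model to synthetic data.

A reduced survey (5 species x 80 stations) is generated with known
community parameters and fitted with the Metropolis-within-Gibbs
sampler; the run prints community hyper-parameter summaries, convergence
diagnostics, and the naive-occupancy bias report.
"""

import numpy as np

from commoccu import (
    CommunityModelSpec,
    GeneratorConfig,
    McmcConfig,
    generate_dataset,
    model_averaged_summary,
    naive_bias_report,
    render_species_table,
    rhat_report,
    run_mcmc,
)

cfg = GeneratorConfig(
    n_species=5, n_sites=80, n_arrays=12,
    occ_covariates=("river", "small_prey"), det_covariates=("road",),
    mu_alpha=(0.0, 1.2), sigma_alpha=(0.8, 0.4),
    mu_beta=(0.4,), sigma_beta=(0.3,),
)
data, covariates, truth = generate_dataset(cfg, seed=5)

spec = CommunityModelSpec(occ_covariates=["river", "small_prey"],
                          det_covariates=["road"])
mcmc = McmcConfig(n_chains=3, n_iter=3000, n_burnin=800, thin=3, seed=5)
samples = run_mcmc(data, covariates, spec, mcmc)

summary = model_averaged_summary(samples)["hyper"]
print(summary.round(2).to_string(index=False))
print(f"\ntruth: mu_phi={cfg.mu_phi}, mu_eta={cfg.mu_eta}, "
      f"mu_alpha={cfg.mu_alpha}, rho={cfg.rho}")
rhat = rhat_report(samples)
print(f"max Rhat = {rhat.max():.3f} (below 1.1 indicates convergence)")
print("\nspecies table (naive vs model-corrected occupancy):")
print(render_species_table(data, samples).to_string(index=False))
bias = naive_bias_report(data, samples)
print(f"\nnaive occupancy is biased low by "
      f"{bias.attrs['mean_abs_bias_pct']:.0f}% on average across species — "
      "the cost of ignoring imperfect detection.")
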