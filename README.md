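# commoccu

Hierarchical multi-species occupancy modeling for camera-trap surveys of
rare and elusive wildlife communities — carnivore guilds in particular —
with imperfect detection, Bayesian covariate selection via inclusion
indicators, and an optional spatial auto-logistic term.

## The problem

Camera-trap surveys of carnivores produce sparse detections: a species
may use a site yet never walk past the camera. Treating non-detection as
absence biases occurrence estimates badly, and the bias is worst for the
rarest species. The remedy is a two-level occupancy model fitted jointly
across the whole community, so that data-rich species lend strength to
data-poor ones, plus spatially explicit covariates (hunting pressure,
patrol effort, prey biomass, habitat descriptors) screened with a formal
model-selection layer.

## The model

Occurrence of species *i* at site *j* is a latent Bernoulli state and
detections are binomial over the site's trap-days:

```
z_ij ~ Bernoulli(psi_ij)
y_ij | z_ij ~ Binomial(k_j, p_ij * z_ij)

logit(psi_ij) = phi_i + alpha_i' x_j + delta_i * autocov_ij
logit(p_ij)   = eta_i + beta_i' v_j
```

Species-level effects are random draws from community-level normal
distributions (e.g. `alpha_ic ~ N(mu_c, sigma_c^2)`); the intercept pair
`(phi_i, eta_i)` is bivariate normal with correlation `rho`, because
abundant species are both more widespread and easier to detect. The
spatial term `autocov_ij` is an inverse-distance weighted average of the
species' occurrence at neighbouring sites within 5 km. Covariate
selection multiplies each covariate by a latent Bernoulli(0.5) inclusion
indicator `w_c` (Kuo–Mallick); posterior indicator frequencies give
covariate inclusion probabilities and posterior model probabilities over
the entire candidate set (2^17 models for the full 10+1 occurrence and 6
detection covariate layout).

Everything is sampled by a bespoke Metropolis-within-Gibbs sampler
written for this model (latent states and indicators by Gibbs, continuous
parameters by adaptive random walk), with classic Gelman–Rubin Rhat
diagnostics.

## Worked example

`examples/04_fit_community_model.py` simulates a 5-species, 80-station
survey with known truth (community occupancy 0.20, detection 0.12, a
planted small-prey effect of +1.2) and fits it:

```
max Rhat = 1.014 (below 1.1 indicates convergence)

species table (naive vs model-corrected occupancy):
species  naive_occupancy   psi  psi_sd     p  p_sd         covariate_effects
    sp3           0.7000 0.692   0.048 0.354 0.013   river(+), small_prey(+)
    sp4           0.2625 0.275   0.041 0.238 0.023   river(+), small_prey(+)
    sp2           0.2125 0.294   0.062 0.070 0.015 river(+80), small_prey(+)
    sp1           0.1000 0.147   0.045 0.081 0.022             small_prey(+)
    sp5           0.0875 0.112   0.034 0.161 0.030             small_prey(+)

naive occupancy is biased low by 24% on average across species
```

Each row compares the raw fraction of stations with a detection
(`naive_occupancy`) against the model's detection-corrected estimate
`psi`; effect flags mark species whose covariate coefficient's credible
interval excludes zero (95%, or 80% where marked). The other examples
cover detection-history construction, covariate-index building
(kernel-density CPUE surfaces, distances, prey biomass, NDVI),
simulation, and model selection.

A thin CLI wraps the same functions:

```sh
commoccu simulate --seed 7 --out sim/
commoccu fit --detections sim/detections_wide.csv --sites sim/sites.csv \
    --covariates sim/site_covariates.csv --model model.yaml --selection --out run/
commoccu report --run run/
```

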