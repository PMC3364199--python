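# Methods

## Model

The package implements a single-season, multi-species site-occupancy
model for detection/non-detection data collected by continuously
operating camera stations. For species *i* = 1..N and station *j* =
1..J:

- latent occurrence `z_ij ~ Bernoulli(psi_ij)`;
- observed detection-day counts `y_ij ~ Binomial(k_j, p_ij)` when
  `z_ij = 1` and structural zeros otherwise, where `k_j` is the
  station's trap-days.

Daily occasions are collapsed to a binomial count. This is exact, not an
approximation: every detection covariate in the model is a station-level
constant, so the per-day Bernoulli likelihood factorises into
`Binomial(k_j, p_ij)` and the collapsed form evaluates the identical
likelihood at a fraction of the cost. Occasion-varying detection
covariates are out of scope.

Link functions are logit-linear:

```
logit(psi_ij) = phi_i + alpha_i' x_j + delta_i * autocov_ij
logit(p_ij)   = eta_i + beta_i' v_j
```

with `x_j` standardized continuous site covariates and `v_j` a mix of
binary design covariates (road, paired cameras, set team, season) and
standardized continuous ones.

Assumptions: the community is closed (every member species was detected
at least once — the model build rejects all-zero detection histories; no
data augmentation for never-detected species); one "season" (no
extinction/colonization dynamics); occurrence means *use* of the site
during the survey rather than permanent occupancy; species respond
independently (no intraguild-interaction terms).

## Community hierarchy and priors

Species-level effects are exchangeable draws from community-level normal
distributions, one `(mu, sigma)` pair per coefficient. The intercept
pair `(phi_i, eta_i)` is bivariate normal with correlation `rho`,
reflecting the shared dependence of occurrence and detectability on
abundance. `rho` couples only the intercepts, not slope pairs — with
N ~ 9 species there is no information to estimate a full cross-coefficient
covariance, and the intercepts are where the abundance signal lives.

Hyperpriors are weakly informative on the probability scale:

| parameter | prior | default | rationale |
|---|---|---|---|
| community means `mu` | Normal(0, 2) | sd 2 (logit scale) | covers psi/p from ~0.02 to ~0.98 without piling mass at the extremes |
| community sds `sigma` | half-Normal(0, 1.5), truncated > 0.01 | — | keeps rare-species shrinkage active; the floor avoids a collapsing-variance spike |
| `rho` | Uniform(−1, 1) | — | no prior directionality |
| inclusion `w_c` | Bernoulli(0.5) | — | uninformative over the candidate set |

All prior constants are overridable through `PriorConfig`.
Fully diffuse priors destabilise rare-species estimates at these sample
sizes; the defaults here play the role that mildly informative
re-specifications play in practice when vague-prior runs fail to
converge.

The model consumes standardized covariates only (mean 0, unit sample
variance, n−1 denominator) and `SiteCovariateTable` enforces that
contract at construction; binary design covariates stay 0/1.

## Spatial autocovariate

The auto-logistic term for station *j* is the inverse-distance weighted
average of the species' current occurrence state at all neighbours
within a 5-km radius (~79 km², spanning short-term individual
movements): weights proportional to 1/d, normalized to sum to one,
stations with empty neighbourhoods contributing 0. During sampling the
autocovariate is recomputed from the current `z` draw after every latent
update; during generation, `z` fields are produced by 50 Gibbs sweeps of
the auto-logistic model from a random start, so stationarity is
approximate by construction (documented, and adequate for recovery
testing).

## Sampler

A bespoke Metropolis-within-Gibbs sampler (the conditionals are coded
here rather than delegated to a general-purpose engine, so the
repository embodies the model):

- **z**: Gibbs, from the closed-form full conditional
  `psi (1-p)^k / [psi (1-p)^k + 1-psi]` for undetected cells; detected
  cells are pinned at 1.
- **species effects**: scalar random-walk Metropolis, proposed for all
  species of one coefficient at once and accepted per species (species
  are conditionally independent given the hyper-parameters and z).
- **community means**: conjugate normal Gibbs draws. Coefficients
  excluded by selection are prior draws and correctly inform their
  hyper-parameters.
- **community sds**: random walk on the log scale with the half-normal
  prior, Jacobian included; proposals below the truncation floor are
  rejected.
- **rho**: random walk on the Fisher-z scale (Jacobian `1 - rho^2`).
- **inclusion indicators**: Gibbs from the Bernoulli full conditional —
  the likelihood ratio of the whole community's data with the covariate
  in versus out, times the prior odds. When `w_c` flips to 0 the species
  coefficients for that covariate are refreshed from their community
  prior (Kuo–Mallick), keeping the dimension fixed; indicators act at
  the community level, switching a covariate for all species at once.

Step sizes adapt toward a 0.44 acceptance rate in blocks of 50
iterations during burn-in only and are frozen afterwards, so the
retained draws come from a fixed transition kernel with the correct
invariant distribution. Chains are seeded by spawning independent
`SeedSequence` streams from the user seed; runs are bit-reproducible.
A non-finite log-posterior at initialization raises with a parameter
dump.

With the autocovariate enabled, the z-update uses the neighbour states
from the current sweep (the standard auto-logistic refresh); this is a
pseudo-Gibbs step, exact when the term is disabled.

## Model selection outputs

Posterior model probabilities are relative frequencies of distinct
indicator vectors among retained draws, rendered as `psi(...) p(...)`
formula strings (the null model prints as `psi(.) p(.)`), sorted by
probability with lexicographic tie-breaks. Model-averaged coefficient
summaries average over draws with `w_c = 1`; a covariate never included
is reported as such rather than silently zero. Credible intervals are
equal-tailed sample quantiles under numpy's linear interpolation
convention; species-level effect flags mark coefficients whose 95% (or,
less conservatively, 80%) interval excludes zero.

The Gelman–Rubin statistic uses the classic between/within form
`sqrt(((n-1)/n W + B/n)/W)` on unsplit chains, matching the diagnostic
convention of the era's Bayesian engines; values below 1.1 are read as
converged. Identical chains give `sqrt((n-1)/n)`, marginally below 1.

## Covariate indices

- **Kernel density**: quartic (biweight) kernel
  `K(d) = (3/pi)(1 - d^2/r^2)^2 / r^2` with a 2-km default radius on
  0.5-km cells. The quartic kernel is the standard GIS choice and
  integrates to the total point weight (verified to ~1% away from grid
  edges; edge cells truncate). The surface is evaluated at cell centres;
  station values are read from the containing cell without
  interpolation.
- **CPUE**: cellwise observation density over effort density. Cells with
  effort below a floor (default 1% of the effort maximum) are masked as
  unsampled instead of producing exploding ratios.
- **Distances**: shapely Euclidean distance; polygons reduce to their
  boundary so interior stations measure distance to the edge. Planar km
  coordinates are assumed throughout; projection is the caller's job.
- **Prey biomass**: deduplicated camera detections (consecutive photos
  of one species at one station under 5 minutes apart chain into a
  single individual) times average adult body mass, per 100 trap-days;
  an 18-kg cutoff produces the small-prey variant.
- **NDVI**: the seasonal measure averages all 16-day composites
  overlapping a station's sampling window; the integrated measure sums
  the gap-free composite series over the study period.
- **Transform/standardize**: optional fourth-root for right-skewed
  nonnegative indices, then z-scoring with the sample sd (n−1). The
  transform is monotone, so ranks survive.
- **Collinearity**: Pearson and Spearman matrices plus VIF from
  regressing each covariate on the rest; perfect collinearity reports an
  infinite VIF with a warning.

## Synthetic-data generator

The generator emulates the survey the model is designed for, and its
defaults are the study conditions: 9 species at 224 stations grouped
into 31 arrays (~7.2 stations each at ~1-km spacing with jitter) in a
40x60 km extent; integer trap-days from a rounded gamma with mean 21.7
and sd 13 clipped to [3, 93]; binary design covariates at the observed
frequencies (90/224 on-road, 17/224 paired, 65/224 second-team, 70%
dry-season); five smooth site covariates drawn from a squared-
exponential Gaussian random field (8-km range, 10% nugget) and
standardized. The generating community has mean occupancy ~0.20
(`mu_phi = -1.4`) and per-day detection ~0.12 (`mu_eta = -2.0`),
intercept correlation 0.47, one strong planted small-prey effect
(`mu = 1.2, sigma = 0.4`), one mixed-sign riverine-like effect
(`mu = 0, sigma = 0.8`) and small-variance null effects elsewhere —
magnitudes chosen once to echo the commonness spectrum and effect
pattern such surveys report (naive occupancies spanning roughly
0.01–0.45), then frozen. Species never detected under a community draw
violate the closure assumption, so the generator redraws the community
(landscape kept) until all species appear.

What the generator does **not** emulate: film exhaustion and camera
failure, animal movement trajectories, patrol routing, real GIS layers,
observation error in patrol records, and any covariate measurement
error. Passing recovery tests therefore demonstrate that the estimator
is consistent with its own generative assumptions at realistic sizes —
not that those assumptions hold in any particular park.

## Validation problem sizes

- Exact-posterior oracle: 2 species x 4 sites, k <= 3, hyper-parameters
  fixed, 3 chains x 20,000 iterations thinned by 2; agreement within 3
  Monte-Carlo standard errors (batch means).
- Parameter recovery: 20 replicate surveys at 9 species x 224 stations,
  fitted with 3 chains x 5,000 iterations (burn-in 1,000, thin 5) with
  selection enabled; pooled 95% CI coverage of the generating
  hyper-parameters compared against the nominal rate with a 3-sigma
  binomial tolerance, and the planted covariate required to attain the
  top inclusion probability in a majority of replicates.
- Prior recovery: an identically-zero design covariate (inclusion
  posterior = prior 0.5, 3 chains x 3,000 unthinned iterations) and a
  zero-site dataset (posterior = prior, checked quantile-by-quantile
  over 4 chains x 40,000 iterations thinned by 10 — prior-only sweeps
  are nearly free, and the long thin run beats the random-walk
  autocorrelation in the tail quantiles) — the latter is the sampler's
  prior predictive mode.

## Known limitations

- The auto-logistic scheme is pseudo-Gibbs during sampling and
  approximate at generation; for strong spatial dependence the
  stationary law is only approached.
- Posterior model probabilities are estimated by indicator-vector
  frequency; models with probability below ~1/draws are invisible.
- Binary design covariates are modeled un-standardized, so their
  coefficient scales differ from the continuous covariates'.
- Single-season closure: surveys spanning true turnover will absorb
  dynamics into psi.
- The sampler is single-threaded; chains run sequentially.
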