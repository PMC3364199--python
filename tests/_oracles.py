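"""Independent brute-force references for the model and sampler tests.

Everything here is written directly from the probabilistic definitions
with scipy.stats, deliberately sharing no code with the package's
likelihood or sampler implementations.
"""

import numpy as np
from scipy.special import expit
from scipy.stats import binom, multivariate_normal


def cell_likelihood(y: int, k: int, psi: float, p: float) -> float:
    """Marginal likelihood of one cell by explicit two-component mixture."""
    present = psi * binom.pmf(y, k, p)
    absent = (1.0 - psi) if y == 0 else 0.0
    return present + absent


def z_posterior(y: int, k: int, psi: float, p: float) -> float:
    """Pr(z=1 | y) by direct Bayes' rule on the mixture components."""
    num = psi * binom.pmf(y, k, p)
    den = num + ((1.0 - psi) if y == 0 else 0.0)
    return num / den


def grid_posterior_means(
    y_i: np.ndarray,
    k: np.ndarray,
    mu_phi: float,
    sigma_phi: float,
    mu_eta: float,
    sigma_eta: float,
    rho: float,
    half_width: float = 7.0,
    n_grid: int = 401,
) -> tuple[float, float]:
    """Exact posterior E[psi], E[p] for one species by 2-D quadrature.

    The species' occurrence/detection intercepts get a bivariate-normal
    prior; the likelihood marginalizes the latent occurrence state.
    """
    g_phi = np.linspace(mu_phi - half_width, mu_phi + half_width, n_grid)
    g_eta = np.linspace(mu_eta - half_width, mu_eta + half_width, n_grid)
    PHI, ETA = np.meshgrid(g_phi, g_eta, indexing="ij")
    cov = np.array(
        [
            [sigma_phi**2, rho * sigma_phi * sigma_eta],
            [rho * sigma_phi * sigma_eta, sigma_eta**2],
        ]
    )
    prior = multivariate_normal([mu_phi, mu_eta], cov).pdf(np.dstack([PHI, ETA]))
    psi, p = expit(PHI), expit(ETA)
    lik = np.ones_like(prior)
    for yj, kj in zip(y_i, k):
        cell = psi * binom.pmf(yj, kj, p)
        if yj == 0:
            cell = cell + (1.0 - psi)
        lik = lik * cell
    post = prior * lik
    z = post.sum()
    return float((post * psi).sum() / z), float((post * p).sum() / z)


def batch_means_mcse(chains: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of a posterior mean from (chains, draws)."""
    m, n = chains.shape
    usable = n - n % n_batches
    bm = chains[:, :usable].reshape(m, n_batches, -1).mean(axis=2)
    return float(bm.std(ddof=1) / np.sqrt(bm.size))
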