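"""The hierarchical multi-species occupancy model as pure functions.

Occurrence of species *i* at site *j* is a latent Bernoulli state
``z[i, j] ~ Bern(psi_ij)`` with
``logit(psi_ij) = phi_i + alpha_i . x_j + delta_i * autocov_ij``;
detections are ``y[i, j] ~ Binomial(k_j, p_ij * z[i, j])`` with
``logit(p_ij) = eta_i + beta_i . v_j``.  Species-level effects are random
draws from community-level normal distributions, with the occurrence and
detection intercepts (phi_i, eta_i) bivariate-normal at correlation rho —
both track species abundance, so common species are both widespread and
easy to detect.

The spatial autocovariate is an auto-logistic term: a normalized
inverse-distance weighted average of the species' current occurrence state
at all neighbours within a fixed radius (5 km default), recomputed from
the current z draw each sampler sweep.

Everything here is sampler-agnostic and cheap enough for brute-force
enumeration oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import expit, gammaln

__all__ = [
    "SpeciesEffects",
    "CommunityHyperparams",
    "PriorConfig",
    "CommunityModelSpec",
    "NeighborhoodGraph",
    "occurrence_prob",
    "detection_prob",
    "autocovariate",
    "site_species_loglik",
    "z_conditional",
    "species_effects_prior_logpdf",
]


@dataclass
class SpeciesEffects:
    """Logit-scale effects for one species."""

    phi: float  # occurrence intercept
    eta: float  # detection intercept
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))  # occurrence slopes
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))  # detection slopes
    delta: float = 0.0  # autocovariate effect

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        vals = [self.phi, self.eta, self.delta, *self.alpha, *self.beta]
        if not np.all(np.isfinite(vals)):
            raise ValueError("species effects must be finite")


@dataclass
class CommunityHyperparams:
    """Community-level means/sds per coefficient and the intercept correlation."""

    mu_phi: float
    sigma_phi: float
    mu_eta: float
    sigma_eta: float
    rho: float = 0.0
    mu_alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mu_beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mu_delta: float = 0.0
    sigma_delta: float = 1.0

    def __post_init__(self) -> None:
        self.mu_alpha = np.atleast_1d(np.asarray(self.mu_alpha, dtype=float))
        self.sigma_alpha = np.atleast_1d(np.asarray(self.sigma_alpha, dtype=float))
        self.mu_beta = np.atleast_1d(np.asarray(self.mu_beta, dtype=float))
        self.sigma_beta = np.atleast_1d(np.asarray(self.sigma_beta, dtype=float))
        sigmas = [self.sigma_phi, self.sigma_eta, self.sigma_delta,
                  *self.sigma_alpha, *self.sigma_beta]
        if np.any(np.asarray(sigmas) <= 0):
            raise ValueError("community sds must be positive")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")


@dataclass
class PriorConfig:
    """Hyperpriors: weakly informative on the probability scale.

    Community means ~ Normal(0, mu_sd); community sds ~ half-Normal(0,
    sigma_sd) truncated above sigma_floor; rho ~ Uniform(-1, 1);
    inclusion indicators ~ Bernoulli(w_prior).
    """

    mu_sd: float = 2.0
    sigma_sd: float = 1.5
    sigma_floor: float = 0.01
    w_prior: float = 0.5


@dataclass
class CommunityModelSpec:
    """Which covariates enter where, plus autocovariate and prior settings."""

    occ_covariates: list[str] = field(default_factory=list)
    det_covariates: list[str] = field(default_factory=list)
    autocovariate: bool = False
    auto_radius_km: float = 5.0
    priors: PriorConfig = field(default_factory=PriorConfig)
    #: hyperparameters to hold fixed instead of sampling (oracle/debug use);
    #: maps names like "mu_phi"/"sigma_phi"/"rho" to values.
    fixed_hyperparams: dict[str, float] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "occ_covariates": list(self.occ_covariates),
            "det_covariates": list(self.det_covariates),
            "autocovariate": self.autocovariate,
            "auto_radius_km": self.auto_radius_km,
            "priors": {
                "mu_sd": self.priors.mu_sd,
                "sigma_sd": self.priors.sigma_sd,
                "sigma_floor": self.priors.sigma_floor,
                "w_prior": self.priors.w_prior,
            },
            "fixed_hyperparams": dict(self.fixed_hyperparams),
        }
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CommunityModelSpec":
        doc = yaml.safe_load(Path(path).read_text())
        priors = PriorConfig(**doc.get("priors", {}))
        return cls(
            occ_covariates=list(doc.get("occ_covariates", [])),
            det_covariates=list(doc.get("det_covariates", [])),
            autocovariate=bool(doc.get("autocovariate", False)),
            auto_radius_km=float(doc.get("auto_radius_km", 5.0)),
            priors=priors,
            fixed_hyperparams=dict(doc.get("fixed_hyperparams", {})),
        )


class NeighborhoodGraph:
    """Inverse-distance neighbourhoods within a radius.

    For each site, neighbours are all other sites within ``radius_km``;
    weights are proportional to 1/distance and normalized to sum to one.
    Sites with no neighbours have empty lists and contribute autocovariate
    0.
    """

    def __init__(self, coords: np.ndarray, radius_km: float = 5.0) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be J x 2")
        if radius_km <= 0:
            raise ValueError("radius must be positive")
        self.radius_km = float(radius_km)
        j = len(coords)
        self.neighbors: list[np.ndarray] = []
        self.weights: list[np.ndarray] = []
        # dense J x J weight matrix for vectorized autocovariate updates
        self.W = np.zeros((j, j))
        d = np.hypot(
            coords[:, 0][:, None] - coords[:, 0][None, :],
            coords[:, 1][:, None] - coords[:, 1][None, :],
        )
        for a in range(j):
            idx = np.nonzero((d[a] <= radius_km) & (np.arange(j) != a))[0]
            if idx.size:
                dists = np.maximum(d[a, idx], 1e-9)
                w = 1.0 / dists
                w = w / w.sum()
            else:
                w = np.zeros(0)
            self.neighbors.append(idx)
            self.weights.append(w)
            self.W[a, idx] = w

    @property
    def n_sites(self) -> int:
        return self.W.shape[0]

    def autocov_matrix(self, z: np.ndarray) -> np.ndarray:
        """N x J autocovariate for an N x J occurrence matrix."""
        return z @ self.W.T


def occurrence_prob(
    effects: SpeciesEffects, x_j: np.ndarray, autocov_j: float = 0.0
) -> float:
    """psi_ij: inverse-logit of phi_i + alpha_i . x_j + delta_i * autocov_j."""
    x_j = np.atleast_1d(np.asarray(x_j, dtype=float))
    if x_j.shape != effects.alpha.shape:
        raise ValueError(
            f"covariate vector length {x_j.shape} does not match alpha {effects.alpha.shape}"
        )
    return float(expit(effects.phi + effects.alpha @ x_j + effects.delta * autocov_j))


def detection_prob(effects: SpeciesEffects, v_j: np.ndarray) -> float:
    """p_ij: inverse-logit of eta_i + beta_i . v_j."""
    v_j = np.atleast_1d(np.asarray(v_j, dtype=float))
    if v_j.shape != effects.beta.shape:
        raise ValueError(
            f"covariate vector length {v_j.shape} does not match beta {effects.beta.shape}"
        )
    return float(expit(effects.eta + effects.beta @ v_j))


def autocovariate(z_i: np.ndarray, graph: NeighborhoodGraph, j: int) -> float:
    """Weighted average occurrence of species i among site j's neighbours."""
    z_i = np.asarray(z_i)
    if z_i.shape[0] != graph.n_sites:
        raise ValueError("z vector length does not match graph")
    idx = graph.neighbors[j]
    if idx.size == 0:
        return 0.0
    return float(graph.weights[j] @ z_i[idx])


def site_species_loglik(y: int, k: int, psi: float, p: float) -> float:
    """Log-likelihood of one (species, site) cell with z marginalized out.

    log[ psi * C(k, y) p^y (1-p)^(k-y) + (1-psi) * 1{y=0} ].
    """
    if not (0 <= y <= k):
        raise ValueError(f"need 0 <= y <= k, got y={y}, k={k}")
    if not (0.0 <= psi <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("psi and p must lie in [0, 1]")
    if (y and p == 0.0) or (k - y and p == 1.0):
        present = 0.0  # impossible outcome under this p
    else:
        log_binom = (
            gammaln(k + 1) - gammaln(y + 1) - gammaln(k - y + 1)
            + (y * math.log(p) if y else 0.0)
            + ((k - y) * math.log1p(-p) if k - y else 0.0)
        )
        present = psi * math.exp(log_binom)
    absent = (1.0 - psi) if y == 0 else 0.0
    total = present + absent
    if total <= 0.0:
        return -math.inf
    return math.log(total)


def z_conditional(y: int, k: int, psi: float, p: float) -> float:
    """Pr(z = 1 | y) for one cell; 1 whenever y >= 1.

    For y = 0: psi (1-p)^k / [psi (1-p)^k + (1-psi)].
    """
    if y >= 1:
        return 1.0
    miss = psi * (1.0 - p) ** k
    denom = miss + (1.0 - psi)
    if denom == 0.0:  # psi = 1, p = 1, k >= 1: presence certain a priori
        return 1.0
    return miss / denom


def _normal_logpdf(x: np.ndarray, mu: float | np.ndarray, sigma: float | np.ndarray) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def species_effects_prior_logpdf(
    effects: SpeciesEffects, hyper: CommunityHyperparams
) -> float:
    """Log-density of one species' effects under the community distribution.

    Independent normals for every slope, plus a bivariate normal with
    correlation rho for the (phi, eta) intercept pair.
    """
    if effects.alpha.shape != hyper.mu_alpha.shape or effects.beta.shape != hyper.mu_beta.shape:
        raise ValueError("effects/hyperparameter coefficient shapes disagree")
    total = float(np.sum(_normal_logpdf(effects.alpha, hyper.mu_alpha, hyper.sigma_alpha)))
    total += float(np.sum(_normal_logpdf(effects.beta, hyper.mu_beta, hyper.sigma_beta)))
    total += float(_normal_logpdf(np.asarray(effects.delta), hyper.mu_delta, hyper.sigma_delta))
    # bivariate normal for the intercept pair
    rho = hyper.rho
    zp = (effects.phi - hyper.mu_phi) / hyper.sigma_phi
    ze = (effects.eta - hyper.mu_eta) / hyper.sigma_eta
    quad = (zp * zp - 2 * rho * zp * ze + ze * ze) / (1 - rho * rho)
    total += -math.log(
        2 * math.pi * hyper.sigma_phi * hyper.sigma_eta * math.sqrt(1 - rho * rho)
    ) - 0.5 * quad
    return total
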