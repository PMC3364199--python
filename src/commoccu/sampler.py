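"""Metropolis-within-Gibbs sampler for the community occupancy model.

The sampler alternates:

* Gibbs draws of the latent occurrence matrix ``z`` from its full
  conditional (cells with a detection are fixed at 1);
* vectorised random-walk Metropolis updates of every species-level
  effect, proposing all species' values of one coefficient at once and
  accepting per species (species are conditionally independent given the
  hyper-parameters and z);
* Gibbs draws of community means (conjugate normal), random-walk updates
  on the log scale for community sds, and a Fisher-z random walk for the
  intercept correlation rho;
* Gibbs draws of the Kuo-Mallick inclusion indicators ``w_c`` from their
  Bernoulli full conditionals (prior 0.5), with excluded coefficients
  refreshed from their community prior so the dimension never changes.

With the spatial term enabled, the autocovariate is refreshed from the
current z draw after every z update (the auto-logistic scheme).  Step
sizes adapt toward a 44% acceptance rate during burn-in only and are
frozen afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .covariates import SiteCovariateTable
from .detection import DESIGN_COLUMNS, DetectionDataset
from .model import CommunityModelSpec, NeighborhoodGraph, PriorConfig

__all__ = ["McmcConfig", "PosteriorSamples", "run_mcmc"]

_DESIGN_INDEX = {name: i for i, name in enumerate(DESIGN_COLUMNS)}
_DESIGN_INDEX["road"] = _DESIGN_INDEX["on_road"]  # common short name


@dataclass
class McmcConfig:
    """Chain layout and tuning.

    ``n_iter`` counts post-burn-in iterations per chain; every ``thin``-th
    one is retained, so each chain keeps ``n_iter // thin`` draws.
    """

    n_chains: int = 3
    n_iter: int = 50_000
    n_burnin: int = 50_000
    thin: int = 50
    seed: int = 0
    target_accept: float = 0.44
    init_step: float = 0.3
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.thin < 1 or self.n_burnin < 0 or self.n_iter < 1 or self.n_chains < 1:
            raise ValueError("invalid MCMC configuration")

    @property
    def draws_per_chain(self) -> int:
        return self.n_iter // self.thin

    @property
    def total_retained_draws(self) -> int:
        return self.n_chains * self.draws_per_chain


@dataclass
class PosteriorSamples:
    """Retained draws, shaped (chains, draws, ...) per parameter.

    ``arrays`` keys: phi/eta/delta (c, d, N); alpha (c, d, N, C_occ);
    beta (c, d, N, C_det); hyper-parameters (c, d) or (c, d, C);
    inclusion indicators w_occ/w_auto/w_det when selection was enabled;
    psi_bar/p_bar/z_mean (c, d, N) — per-species means over sites of
    occurrence probability, detection probability and latent occurrence.
    """

    arrays: dict[str, np.ndarray]
    species: list[str]
    occ_names: list[str]
    det_names: list[str]
    selection: bool
    autocovariate: bool
    accept_rates: dict[str, float]
    config: McmcConfig
    spec: CommunityModelSpec

    @property
    def n_chains(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.arrays.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (chains * draws, ...)."""
        a = self.arrays[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def inclusion_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Pooled (draws, C_total) indicator matrix and covariate labels."""
        if not self.selection:
            raise ValueError("model selection was not enabled for this run")
        blocks = [self.stacked("w_occ")]
        labels = [f"psi:{n}" for n in self.occ_names]
        if self.autocovariate:
            blocks.append(self.stacked("w_auto")[:, None])
            labels.append("psi:autocov")
        blocks.append(self.stacked("w_det"))
        labels += [f"p:{n}" for n in self.det_names]
        return np.concatenate(blocks, axis=1).astype(int), labels


def _occ_ll(lp: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-species occurrence log-likelihood: sum_j z lp - log(1 + e^lp)."""
    return (z * lp - np.logaddexp(0.0, lp)).sum(axis=1)


def _det_ll(lp: np.ndarray, z: np.ndarray, y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Per-species detection log-likelihood (binomial, z-gated, no constant)."""
    return (z * (y * lp - k[None, :] * np.logaddexp(0.0, lp))).sum(axis=1)


def _norm_lpdf(x, mu, sigma):
    return -0.5 * math.log(2 * math.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


class _Adaptive:
    """A scalar random-walk step size with Robbins-Monro-style adaptation."""

    def __init__(self, step: float, target: float, interval: int) -> None:
        self.step = step
        self.target = target
        self.interval = interval
        self.n = 0
        self.accepted = 0.0

    def record(self, rate: float, adapting: bool) -> None:
        self.accepted += rate
        self.n += 1
        if adapting and self.n % self.interval == 0:
            recent = self.accepted / self.n
            self.step *= math.exp(recent - self.target)
            self.n = 0
            self.accepted = 0.0


class _ChainState:
    """Mutable state of one chain; owns its RNG and step sizes."""

    def __init__(
        self,
        data: DetectionDataset,
        x: np.ndarray,
        v: np.ndarray,
        spec: CommunityModelSpec,
        cfg: McmcConfig,
        graph: NeighborhoodGraph | None,
        selection: bool,
        rng: np.random.Generator,
    ) -> None:
        self.rng = rng
        self.spec = spec
        self.selection = selection
        self.graph = graph
        self.y = data.y.astype(float)
        self.k = data.k.astype(float)
        self.y_pos = data.y > 0
        self.x = x  # J x C_occ standardized
        self.v = v  # J x C_det
        n, j = data.y.shape
        self.n, self.j = n, j
        c_occ, c_det = x.shape[1], v.shape[1]
        self.c_occ, self.c_det = c_occ, c_det
        pri = spec.priors

        # species effects: start near the community prior centre
        self.phi = rng.normal(0.0, 0.5, n)
        self.eta = rng.normal(0.0, 0.5, n)
        self.alpha = rng.normal(0.0, 0.25, (n, c_occ))
        self.beta = rng.normal(0.0, 0.25, (n, c_det))
        self.delta = rng.normal(0.0, 0.25, n) if spec.autocovariate else np.zeros(n)

        # hyper-parameters
        self.hyper: dict[str, np.ndarray | float] = {
            "mu_phi": 0.0,
            "sigma_phi": 1.0,
            "mu_eta": 0.0,
            "sigma_eta": 1.0,
            "rho": 0.0,
            "mu_alpha": np.zeros(c_occ),
            "sigma_alpha": np.ones(c_occ),
            "mu_beta": np.zeros(c_det),
            "sigma_beta": np.ones(c_det),
            "mu_delta": 0.0,
            "sigma_delta": 1.0,
        }
        self.fixed = set()
        for name, value in spec.fixed_hyperparams.items():
            if name not in self.hyper:
                raise KeyError(f"unknown hyper-parameter {name!r}")
            if isinstance(self.hyper[name], np.ndarray):
                self.hyper[name] = np.broadcast_to(
                    np.asarray(value, dtype=float), self.hyper[name].shape
                ).copy()
            else:
                self.hyper[name] = float(value)
            self.fixed.add(name)

        # inclusion indicators (all in when selection is off)
        self.w_occ = np.ones(c_occ, dtype=int)
        self.w_auto = 1 if spec.autocovariate else 0
        self.w_det = np.ones(c_det, dtype=int)

        # latent occurrence: detections force presence
        self.z = np.where(self.y_pos, 1.0, (rng.random((n, j)) < 0.5).astype(float))
        self.autocov = graph.autocov_matrix(self.z) if graph is not None else np.zeros((n, j))

        self.lp_psi = self._lp_psi()
        self.lp_p = self._lp_p()

        tgt, ival = cfg.target_accept, cfg.adapt_interval
        s = cfg.init_step
        self.steps: dict[str, _Adaptive] = {"phi": _Adaptive(s, tgt, ival), "eta": _Adaptive(s, tgt, ival)}
        for c in range(c_occ):
            self.steps[f"alpha{c}"] = _Adaptive(s, tgt, ival)
        for c in range(c_det):
            self.steps[f"beta{c}"] = _Adaptive(s, tgt, ival)
        if spec.autocovariate:
            self.steps["delta"] = _Adaptive(s, tgt, ival)
        for hname in ("mu_phi", "sigma_phi", "mu_eta", "sigma_eta", "rho"):
            self.steps[hname] = _Adaptive(s, tgt, ival)
        for c in range(c_occ):
            self.steps[f"sigma_alpha{c}"] = _Adaptive(s, tgt, ival)
        for c in range(c_det):
            self.steps[f"sigma_beta{c}"] = _Adaptive(s, tgt, ival)
        if spec.autocovariate:
            self.steps["sigma_delta"] = _Adaptive(s, tgt, ival)
        self.pri: PriorConfig = pri

        if not np.all(np.isfinite(self._log_posterior_core())):
            raise FloatingPointError(
                "non-finite log-posterior at initialization; state: "
                f"phi={self.phi}, eta={self.eta}, hyper={self.hyper}"
            )

    # -- linear predictors --------------------------------------------------

    def _lp_psi(self) -> np.ndarray:
        lp = self.phi[:, None] + (self.alpha * self.w_occ) @ self.x.T
        if self.spec.autocovariate and self.w_auto:
            lp = lp + self.delta[:, None] * self.autocov
        return lp

    def _lp_p(self) -> np.ndarray:
        return self.eta[:, None] + (self.beta * self.w_det) @ self.v.T

    def _log_posterior_core(self) -> np.ndarray:
        return _occ_ll(self.lp_psi, self.z) + _det_ll(self.lp_p, self.z, self.y, self.k)

    def _biv_prior(self, phi: np.ndarray, eta: np.ndarray) -> np.ndarray:
        h = self.hyper
        rho = float(h["rho"])
        zp = (phi - h["mu_phi"]) / h["sigma_phi"]
        ze = (eta - h["mu_eta"]) / h["sigma_eta"]
        return (
            -math.log(2 * math.pi * h["sigma_phi"] * h["sigma_eta"] * math.sqrt(1 - rho**2))
            - (zp**2 - 2 * rho * zp * ze + ze**2) / (2 * (1 - rho**2))
        )

    # -- updates ------------------------------------------------------------

    def update_z(self) -> None:
        """Gibbs draw of latent occurrence; autocovariate refreshed after."""
        psi = expit(self.lp_psi)
        log_miss = -self.k[None, :] * np.logaddexp(0.0, self.lp_p)  # log (1-p)^k
        num = psi * np.exp(log_miss)
        pz = num / (num + (1.0 - psi))
        draw = (self.rng.random((self.n, self.j)) < pz).astype(float)
        self.z = np.where(self.y_pos, 1.0, draw)
        if self.graph is not None:
            self.autocov = self.graph.autocov_matrix(self.z)
            self.lp_psi = self._lp_psi()

    def _mh_species(
        self,
        key: str,
        current: np.ndarray,
        logpost: "callable",
        adapting: bool,
    ) -> np.ndarray:
        """Vectorised per-species scalar Metropolis step.

        ``logpost(vals)`` must return the per-species log-posterior terms
        that depend on the updated quantity.
        """
        step = self.steps[key]
        prop = current + step.step * self.rng.standard_normal(self.n)
        lp0 = logpost(current)
        lp1 = logpost(prop)
        accept = np.log(self.rng.random(self.n)) < (lp1 - lp0)
        out = np.where(accept, prop, current)
        step.record(float(accept.mean()), adapting)
        return out

    def update_phi(self, adapting: bool) -> None:
        def logpost(vals: np.ndarray) -> np.ndarray:
            lp = self.lp_psi + (vals - self.phi)[:, None]
            return _occ_ll(lp, self.z) + self._biv_prior(vals, self.eta)

        new = self._mh_species("phi", self.phi, logpost, adapting)
        self.lp_psi += (new - self.phi)[:, None]
        self.phi = new

    def update_eta(self, adapting: bool) -> None:
        def logpost(vals: np.ndarray) -> np.ndarray:
            lp = self.lp_p + (vals - self.eta)[:, None]
            return _det_ll(lp, self.z, self.y, self.k) + self._biv_prior(self.phi, vals)

        new = self._mh_species("eta", self.eta, logpost, adapting)
        self.lp_p += (new - self.eta)[:, None]
        self.eta = new

    def update_alpha(self, adapting: bool) -> None:
        h = self.hyper
        for c in range(self.c_occ):
            mu_c = h["mu_alpha"][c]
            sd_c = h["sigma_alpha"][c]
            if self.selection and self.w_occ[c] == 0:
                # excluded: coefficient has no likelihood; refresh from prior
                self.alpha[:, c] = self.rng.normal(mu_c, sd_c, self.n)
                continue
            xc = self.x[:, c][None, :]
            cur = self.alpha[:, c]

            def logpost(vals: np.ndarray) -> np.ndarray:
                lp = self.lp_psi + (vals - cur)[:, None] * xc
                return _occ_ll(lp, self.z) + _norm_lpdf(vals, mu_c, sd_c)

            new = self._mh_species(f"alpha{c}", cur, logpost, adapting)
            self.lp_psi += (new - cur)[:, None] * xc
            self.alpha[:, c] = new

    def update_delta(self, adapting: bool) -> None:
        if not self.spec.autocovariate:
            return
        h = self.hyper
        if self.selection and self.w_auto == 0:
            self.delta = self.rng.normal(h["mu_delta"], h["sigma_delta"], self.n)
            return
        cur = self.delta

        def logpost(vals: np.ndarray) -> np.ndarray:
            lp = self.lp_psi + (vals - cur)[:, None] * self.autocov
            return _occ_ll(lp, self.z) + _norm_lpdf(vals, h["mu_delta"], h["sigma_delta"])

        new = self._mh_species("delta", cur, logpost, adapting)
        self.lp_psi += (new - cur)[:, None] * self.autocov
        self.delta = new

    def update_beta(self, adapting: bool) -> None:
        h = self.hyper
        for c in range(self.c_det):
            mu_c = h["mu_beta"][c]
            sd_c = h["sigma_beta"][c]
            if self.selection and self.w_det[c] == 0:
                self.beta[:, c] = self.rng.normal(mu_c, sd_c, self.n)
                continue
            vc = self.v[:, c][None, :]
            cur = self.beta[:, c]

            def logpost(vals: np.ndarray) -> np.ndarray:
                lp = self.lp_p + (vals - cur)[:, None] * vc
                return _det_ll(lp, self.z, self.y, self.k) + _norm_lpdf(vals, mu_c, sd_c)

            new = self._mh_species(f"beta{c}", cur, logpost, adapting)
            self.lp_p += (new - cur)[:, None] * vc
            self.beta[:, c] = new

    def update_inclusion(self) -> None:
        """Gibbs draws of the Kuo-Mallick indicators from their Bernoulli
        full conditionals (community-level: one indicator per covariate)."""
        if not self.selection:
            return
        logit_prior = math.log(self.pri.w_prior) - math.log1p(-self.pri.w_prior)
        for c in range(self.c_occ):
            contrib = self.alpha[:, c][:, None] * self.x[:, c][None, :]
            lp_without = self.lp_psi - (self.w_occ[c] * contrib)
            ll0 = _occ_ll(lp_without, self.z).sum()
            ll1 = _occ_ll(lp_without + contrib, self.z).sum()
            pr1 = expit(ll1 - ll0 + logit_prior)
            new = int(self.rng.random() < pr1)
            if new != self.w_occ[c]:
                self.w_occ[c] = new
                self.lp_psi = lp_without + (contrib if new else 0.0)
        if self.spec.autocovariate:
            contrib = self.delta[:, None] * self.autocov
            lp_without = self.lp_psi - (self.w_auto * contrib)
            ll0 = _occ_ll(lp_without, self.z).sum()
            ll1 = _occ_ll(lp_without + contrib, self.z).sum()
            pr1 = expit(ll1 - ll0 + logit_prior)
            new = int(self.rng.random() < pr1)
            if new != self.w_auto:
                self.w_auto = new
                self.lp_psi = lp_without + (contrib if new else 0.0)
        for c in range(self.c_det):
            contrib = self.beta[:, c][:, None] * self.v[:, c][None, :]
            lp_without = self.lp_p - (self.w_det[c] * contrib)
            ll0 = _det_ll(lp_without, self.z, self.y, self.k).sum()
            ll1 = _det_ll(lp_without + contrib, self.z, self.y, self.k).sum()
            pr1 = expit(ll1 - ll0 + logit_prior)
            new = int(self.rng.random() < pr1)
            if new != self.w_det[c]:
                self.w_det[c] = new
                self.lp_p = lp_without + (contrib if new else 0.0)

    # -- hyper-parameter updates ---------------------------------------------

    def _gibbs_mean(self, values: np.ndarray, sigma: float) -> float:
        """Conjugate normal draw for a community mean (prior N(0, mu_sd))."""
        prec = len(values) / sigma**2 + 1.0 / self.pri.mu_sd**2
        mean = values.sum() / sigma**2 / prec
        return float(self.rng.normal(mean, 1.0 / math.sqrt(prec)))

    def _mh_scalar(self, key: str, current: float, logpost, adapting: bool) -> float:
        step = self.steps[key]
        prop = current + step.step * self.rng.standard_normal()
        lp0 = logpost(current)
        lp1 = logpost(prop)
        if not np.isfinite(lp1):
            accept = False
        else:
            accept = math.log(self.rng.random()) < (lp1 - lp0)
        step.record(float(accept), adapting)
        return prop if accept else current

    def _halfnormal_lpdf(self, sigma: float) -> float:
        if sigma <= self.pri.sigma_floor:
            return -math.inf
        return -0.5 * (sigma / self.pri.sigma_sd) ** 2

    def update_hyper(self, adapting: bool) -> None:
        h = self.hyper
        # slope means: conjugate Gibbs (excluded coefficients are prior
        # draws, so they still inform the community mean correctly)
        if "mu_alpha" not in self.fixed:
            for c in range(self.c_occ):
                h["mu_alpha"][c] = self._gibbs_mean(self.alpha[:, c], h["sigma_alpha"][c])
        if "mu_beta" not in self.fixed:
            for c in range(self.c_det):
                h["mu_beta"][c] = self._gibbs_mean(self.beta[:, c], h["sigma_beta"][c])
        if self.spec.autocovariate and "mu_delta" not in self.fixed:
            h["mu_delta"] = self._gibbs_mean(self.delta, float(h["sigma_delta"]))

        # slope sds: log-scale random walk under the half-normal prior
        if "sigma_alpha" not in self.fixed:
            for c in range(self.c_occ):
                mu_c = h["mu_alpha"][c]
                vals = self.alpha[:, c]

                def logpost(log_s: float) -> float:
                    s = math.exp(log_s)
                    return (
                        float(_norm_lpdf(vals, mu_c, s).sum())
                        + self._halfnormal_lpdf(s)
                        + log_s  # Jacobian of the log transform
                    )

                new = self._mh_scalar(
                    f"sigma_alpha{c}", math.log(h["sigma_alpha"][c]), logpost, adapting
                )
                h["sigma_alpha"][c] = math.exp(new)
        if "sigma_beta" not in self.fixed:
            for c in range(self.c_det):
                mu_c = h["mu_beta"][c]
                vals = self.beta[:, c]

                def logpost(log_s: float) -> float:
                    s = math.exp(log_s)
                    return (
                        float(_norm_lpdf(vals, mu_c, s).sum())
                        + self._halfnormal_lpdf(s)
                        + log_s
                    )

                new = self._mh_scalar(
                    f"sigma_beta{c}", math.log(h["sigma_beta"][c]), logpost, adapting
                )
                h["sigma_beta"][c] = math.exp(new)
        if self.spec.autocovariate and "sigma_delta" not in self.fixed:
            def logpost_d(log_s: float) -> float:
                s = math.exp(log_s)
                return (
                    float(_norm_lpdf(self.delta, float(h["mu_delta"]), s).sum())
                    + self._halfnormal_lpdf(s)
                    + log_s
                )

            new = self._mh_scalar(
                "sigma_delta", math.log(float(h["sigma_delta"])), logpost_d, adapting
            )
            h["sigma_delta"] = math.exp(new)

        # intercept pair: random-walk Metropolis on each scalar
        def biv_total() -> float:
            return float(self._biv_prior(self.phi, self.eta).sum())

        if "mu_phi" not in self.fixed:
            def logpost_mp(val: float) -> float:
                old = h["mu_phi"]
                h["mu_phi"] = val
                out = biv_total() + float(_norm_lpdf(np.asarray(val), 0.0, self.pri.mu_sd))
                h["mu_phi"] = old
                return out

            h["mu_phi"] = self._mh_scalar("mu_phi", float(h["mu_phi"]), logpost_mp, adapting)
        if "mu_eta" not in self.fixed:
            def logpost_me(val: float) -> float:
                old = h["mu_eta"]
                h["mu_eta"] = val
                out = biv_total() + float(_norm_lpdf(np.asarray(val), 0.0, self.pri.mu_sd))
                h["mu_eta"] = old
                return out

            h["mu_eta"] = self._mh_scalar("mu_eta", float(h["mu_eta"]), logpost_me, adapting)
        if "sigma_phi" not in self.fixed:
            def logpost_sp(log_s: float) -> float:
                s = math.exp(log_s)
                old = h["sigma_phi"]
                h["sigma_phi"] = s
                out = biv_total() + self._halfnormal_lpdf(s) + log_s
                h["sigma_phi"] = old
                return out

            h["sigma_phi"] = math.exp(
                self._mh_scalar("sigma_phi", math.log(float(h["sigma_phi"])), logpost_sp, adapting)
            )
        if "sigma_eta" not in self.fixed:
            def logpost_se(log_s: float) -> float:
                s = math.exp(log_s)
                old = h["sigma_eta"]
                h["sigma_eta"] = s
                out = biv_total() + self._halfnormal_lpdf(s) + log_s
                h["sigma_eta"] = old
                return out

            h["sigma_eta"] = math.exp(
                self._mh_scalar("sigma_eta", math.log(float(h["sigma_eta"])), logpost_se, adapting)
            )
        if "rho" not in self.fixed:
            # Fisher-z walk; uniform(-1, 1) prior on rho gives Jacobian 1 - rho^2
            def logpost_r(zval: float) -> float:
                r = math.tanh(zval)
                old = h["rho"]
                h["rho"] = r
                out = biv_total() + math.log1p(-r * r)
                h["rho"] = old
                return out

            znew = self._mh_scalar("rho", math.atanh(float(h["rho"])), logpost_r, adapting)
            h["rho"] = math.tanh(znew)

    def sweep(self, adapting: bool) -> None:
        self.update_z()
        self.update_phi(adapting)
        self.update_eta(adapting)
        self.update_alpha(adapting)
        self.update_delta(adapting)
        self.update_beta(adapting)
        self.update_inclusion()
        self.update_hyper(adapting)


def _build_det_matrix(
    data: DetectionDataset, covariates: SiteCovariateTable | None, names: Sequence[str]
) -> np.ndarray:
    """Detection design matrix: binary design columns by name, otherwise
    standardized site covariates."""
    cols = []
    for name in names:
        if name in _DESIGN_INDEX:
            cols.append(data.design[:, _DESIGN_INDEX[name]].astype(float))
        else:
            if covariates is None:
                raise KeyError(f"detection covariate {name!r} needs a site covariate table")
            cols.append(covariates.matrix([name])[:, 0])
    return np.column_stack(cols) if cols else np.zeros((data.n_sites, 0))


def run_mcmc(
    data: DetectionDataset,
    covariates: SiteCovariateTable | None,
    spec: CommunityModelSpec,
    cfg: McmcConfig,
    selection: bool = False,
) -> PosteriorSamples:
    """Fit the community model; reproducible given ``cfg.seed``.

    ``covariates`` may be None when the spec names no site covariates.
    With ``selection`` enabled, inclusion indicators are sampled alongside
    everything else (Kuo-Mallick mixture run); otherwise the full model is
    fitted with every covariate in.

    A dataset with zero sites is accepted (build it with
    ``require_closure=False``): the likelihood is then empty, every
    parameter posterior equals its prior, and the run serves as a prior
    predictive check.
    """
    if covariates is not None and covariates.n_sites != data.n_sites:
        raise ValueError("detection data and covariate table have different site counts")
    if data.n_sites and np.any(data.y.sum(axis=1) == 0):
        never = [s for s, row in zip(data.species, data.y) if row.sum() == 0]
        raise ValueError(
            f"species never detected: {never}; the model assumes every "
            "community member was detected at least once"
        )
    x = (
        covariates.matrix(spec.occ_covariates)
        if spec.occ_covariates
        else np.zeros((data.n_sites, 0))
    )
    v = _build_det_matrix(data, covariates, spec.det_covariates)
    graph = (
        NeighborhoodGraph(data.coords, spec.auto_radius_km) if spec.autocovariate else None
    )

    n, j = data.n_species, data.n_sites
    c_occ, c_det = x.shape[1], v.shape[1]
    d = cfg.draws_per_chain
    shapes: dict[str, tuple] = {
        "phi": (n,), "eta": (n,), "delta": (n,),
        "alpha": (n, c_occ), "beta": (n, c_det),
        "mu_phi": (), "sigma_phi": (), "mu_eta": (), "sigma_eta": (), "rho": (),
        "mu_alpha": (c_occ,), "sigma_alpha": (c_occ,),
        "mu_beta": (c_det,), "sigma_beta": (c_det,),
        "mu_delta": (), "sigma_delta": (),
        "psi_bar": (n,), "p_bar": (n,), "z_mean": (n,),
    }
    if selection:
        shapes.update({"w_occ": (c_occ,), "w_auto": (), "w_det": (c_det,)})
    out = {k_: np.zeros((cfg.n_chains, d, *shp)) for k_, shp in shapes.items()}

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    accept_tot: dict[str, list[float]] = {}
    for chain, seed_seq in enumerate(seeds):
        rng = np.random.default_rng(seed_seq)
        state = _ChainState(data, x, v, spec, cfg, graph, selection, rng)
        for _ in range(cfg.n_burnin):
            state.sweep(adapting=True)
        # freeze step sizes; reset acceptance bookkeeping for reporting
        for ad in state.steps.values():
            ad.n = 0
            ad.accepted = 0.0
        kept = 0
        for it in range(cfg.n_iter):
            state.sweep(adapting=False)
            if (it + 1) % cfg.thin == 0 and kept < d:
                h = state.hyper
                rec = {
                    "phi": state.phi, "eta": state.eta, "delta": state.delta,
                    "alpha": state.alpha, "beta": state.beta,
                    "mu_phi": h["mu_phi"], "sigma_phi": h["sigma_phi"],
                    "mu_eta": h["mu_eta"], "sigma_eta": h["sigma_eta"],
                    "rho": h["rho"],
                    "mu_alpha": h["mu_alpha"], "sigma_alpha": h["sigma_alpha"],
                    "mu_beta": h["mu_beta"], "sigma_beta": h["sigma_beta"],
                    "mu_delta": h["mu_delta"], "sigma_delta": h["sigma_delta"],
                    "psi_bar": expit(state.lp_psi).mean(axis=1) if j else np.full(n, np.nan),
                    "p_bar": expit(state.lp_p).mean(axis=1) if j else np.full(n, np.nan),
                    "z_mean": state.z.mean(axis=1) if j else np.full(n, np.nan),
                }
                if selection:
                    rec.update(
                        {"w_occ": state.w_occ, "w_auto": state.w_auto, "w_det": state.w_det}
                    )
                for k_, val in rec.items():
                    out[k_][chain, kept] = val
                kept += 1
        for key, ad in state.steps.items():
            if ad.n:
                accept_tot.setdefault(key, []).append(ad.accepted / ad.n)

    accept_rates = {k_: float(np.mean(v_)) for k_, v_ in accept_tot.items()}
    return PosteriorSamples(
        arrays=out,
        species=list(data.species),
        occ_names=list(spec.occ_covariates),
        det_names=list(spec.det_covariates),
        selection=selection,
        autocovariate=spec.autocovariate,
        accept_rates=accept_rates,
        config=cfg,
        spec=spec,
    )
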