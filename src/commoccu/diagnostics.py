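"""Convergence diagnostics, model selection summaries and posterior tables.

Covers the Gelman-Rubin potential scale reduction factor (classic
between/within-chain form, convergence flagged below 1.1), posterior
inclusion probabilities and posterior model probabilities from the
Kuo-Mallick indicator draws, model-averaged coefficient summaries with
80%/95% equal-tailed credible intervals, marginal occurrence curves, and
the naive-versus-model occupancy bias report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .detection import DetectionDataset, naive_occupancy
from .model import CommunityModelSpec
from .sampler import PosteriorSamples

__all__ = [
    "gelman_rubin",
    "rhat_report",
    "inclusion_probabilities",
    "posterior_model_table",
    "model_averaged_summary",
    "candidate_set_size",
    "predict_marginal_occurrence",
    "naive_bias_report",
    "format_model",
]

RHAT_THRESHOLD = 1.1


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is (m, n): m >= 2 chains of n draws.  With within-chain
    variance W and between-chain variance B (of chain means, times n),
    Rhat = sqrt(((n-1)/n W + B/n) / W).  Values near 1 indicate the
    chains are sampling the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need at least 2 draws per chain")
    w = chains.var(axis=1, ddof=1).mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0  # constant chains: nothing to reduce
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def rhat_report(samples: PosteriorSamples) -> pd.Series:
    """Rhat for every scalar hyper-parameter and species intercept."""
    out = {}
    for name in ("mu_phi", "sigma_phi", "mu_eta", "sigma_eta", "rho"):
        out[name] = gelman_rubin(samples.arrays[name])
    for vec, label in (("mu_alpha", "mu_alpha"), ("mu_beta", "mu_beta")):
        arr = samples.arrays[vec]
        names = samples.occ_names if vec == "mu_alpha" else samples.det_names
        for c, cname in enumerate(names):
            out[f"{label}[{cname}]"] = gelman_rubin(arr[:, :, c])
    phi = samples.arrays["phi"]
    eta = samples.arrays["eta"]
    for i, sp in enumerate(samples.species):
        out[f"phi[{sp}]"] = gelman_rubin(phi[:, :, i])
        out[f"eta[{sp}]"] = gelman_rubin(eta[:, :, i])
    return pd.Series(out, name="rhat")


def inclusion_probabilities(samples: PosteriorSamples) -> pd.Series:
    """Posterior Pr(w_c = 1) per candidate covariate."""
    w, labels = samples.inclusion_matrix()
    return pd.Series(w.mean(axis=0), index=labels, name="inclusion_probability")


def format_model(pattern: np.ndarray, labels: list[str]) -> str:
    """Render an inclusion pattern as a psi(...) p(...) formula string.

    Empty sides render as a dot: ``psi(.) p(.)`` is the null model.
    """
    occ = [l.split(":", 1)[1] for l, w in zip(labels, pattern) if w and l.startswith("psi:")]
    det = [l.split(":", 1)[1] for l, w in zip(labels, pattern) if w and l.startswith("p:")]
    return f"psi({' + '.join(occ) if occ else '.'}) p({' + '.join(det) if det else '.'})"


def posterior_model_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior model probabilities from indicator-pattern frequencies.

    Each distinct inclusion vector in the posterior sample is one
    candidate model; its probability is its relative frequency.  Rows are
    sorted by probability descending, ties broken lexicographically on
    the pattern.
    """
    w, labels = samples.inclusion_matrix()
    patterns, counts = np.unique(w, axis=0, return_counts=True)
    probs = counts / w.shape[0]
    order = sorted(
        range(len(probs)), key=lambda i: (-probs[i], tuple(patterns[i]))
    )
    rows = [
        {
            "model": format_model(patterns[i], labels),
            "posterior_probability": probs[i],
            "pattern": "".join(map(str, patterns[i])),
        }
        for i in order
    ]
    return pd.DataFrame(rows)


def candidate_set_size(spec: CommunityModelSpec) -> int:
    """Number of candidate models: 2^(selectable covariates)."""
    c = len(spec.occ_covariates) + len(spec.det_covariates) + (1 if spec.autocovariate else 0)
    return 2**c


def _interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    lo = (1 - level) / 2
    return (
        float(np.quantile(draws, lo)),
        float(np.quantile(draws, 1 - lo)),
    )


def _effect_flag(draws: np.ndarray) -> tuple[str, int] | None:
    """Sign and threshold when an equal-tailed CI excludes zero.

    Returns ('+' or '-', 95) when the 95% CI excludes zero, the same with
    80 when only the 80% CI does, and None otherwise.
    """
    lo95, hi95 = _interval(draws, 0.95)
    if lo95 > 0:
        return "+", 95
    if hi95 < 0:
        return "-", 95
    lo80, hi80 = _interval(draws, 0.80)
    if lo80 > 0:
        return "+", 80
    if hi80 < 0:
        return "-", 80
    return None


def model_averaged_summary(samples: PosteriorSamples) -> dict[str, pd.DataFrame]:
    """Posterior summaries: hyper-parameters, species parameters, effects.

    Credible intervals are equal-tailed sample quantiles (numpy linear
    interpolation).  Under selection, covariate coefficients are
    model-averaged over draws with the covariate included (w_c = 1); a
    covariate never included is reported as not included.
    """
    hyper_rows = []

    def add_hyper(name: str, draws: np.ndarray, w: np.ndarray | None = None) -> None:
        label = name
        if w is not None:
            incl = w.astype(bool)
            if not incl.any():
                hyper_rows.append(
                    {"parameter": label, "mean": np.nan, "sd": np.nan,
                     "ci95_lo": np.nan, "ci95_hi": np.nan,
                     "ci80_lo": np.nan, "ci80_hi": np.nan,
                     "note": "not included in any posterior draw"}
                )
                return
            draws = draws[incl]
        lo95, hi95 = _interval(draws, 0.95)
        lo80, hi80 = _interval(draws, 0.80)
        hyper_rows.append(
            {"parameter": label, "mean": float(draws.mean()),
             "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
             "ci95_lo": lo95, "ci95_hi": hi95, "ci80_lo": lo80, "ci80_hi": hi80,
             "note": ""}
        )

    sel = samples.selection
    for name in ("mu_phi", "sigma_phi", "mu_eta", "sigma_eta", "rho"):
        add_hyper(name, samples.stacked(name))
    w_occ = samples.stacked("w_occ") if sel else None
    w_det = samples.stacked("w_det") if sel else None
    for c, cname in enumerate(samples.occ_names):
        add_hyper(
            f"mu_alpha[{cname}]",
            samples.stacked("mu_alpha")[:, c],
            w_occ[:, c] if sel else None,
        )
    if samples.autocovariate:
        add_hyper(
            "mu_delta",
            samples.stacked("mu_delta"),
            samples.stacked("w_auto") if sel else None,
        )
    for c, cname in enumerate(samples.det_names):
        add_hyper(
            f"mu_beta[{cname}]",
            samples.stacked("mu_beta")[:, c],
            w_det[:, c] if sel else None,
        )
    hyper = pd.DataFrame(hyper_rows)

    # per-species summaries of psi-bar / p-bar and effect flags
    sp_rows = []
    psi_bar = samples.stacked("psi_bar")
    p_bar = samples.stacked("p_bar")
    alpha = samples.stacked("alpha")
    for i, sp in enumerate(samples.species):
        flags = []
        for c, cname in enumerate(samples.occ_names):
            draws = alpha[:, i, c]
            if sel:
                incl = w_occ[:, c].astype(bool)
                if not incl.any():
                    continue
                draws = draws[incl]
            flag = _effect_flag(draws)
            if flag is not None:
                sign, level = flag
                suffix = f"({sign})" if level == 95 else f"({sign}80)"
                flags.append(f"{cname}{suffix}")
        sp_rows.append(
            {
                "species": sp,
                "psi_mean": float(psi_bar[:, i].mean()),
                "psi_sd": float(psi_bar[:, i].std(ddof=1)),
                "p_mean": float(p_bar[:, i].mean()),
                "p_sd": float(p_bar[:, i].std(ddof=1)),
                "effects": ", ".join(flags),
            }
        )
    species = pd.DataFrame(sp_rows)
    return {"hyper": hyper, "species": species}


def predict_marginal_occurrence(
    samples: PosteriorSamples,
    species: str,
    covariate: str,
    grid: np.ndarray,
) -> pd.DataFrame:
    """Posterior-mean occurrence versus one standardized covariate.

    Other covariates are held at their standardized mean (0), so each
    grid point averages inverse-logit(phi_i + alpha_ic x) over the
    posterior draws.
    """
    if species not in samples.species:
        raise KeyError(f"unknown species {species!r}")
    if covariate not in samples.occ_names:
        raise KeyError(f"covariate {covariate!r} is not in the occurrence model")
    i = samples.species.index(species)
    c = samples.occ_names.index(covariate)
    phi = samples.stacked("phi")[:, i]
    alpha = samples.stacked("alpha")[:, i, c]
    if samples.selection:
        alpha = alpha * samples.stacked("w_occ")[:, c]
    grid = np.asarray(grid, dtype=float)
    psi = expit(phi[None, :] + alpha[None, :] * grid[:, None]).mean(axis=1)
    return pd.DataFrame({"x": grid, "psi": psi})


def naive_bias_report(data: DetectionDataset, samples: PosteriorSamples) -> pd.DataFrame:
    """Relative bias of naive occupancy against the model estimate.

    Per species: 100 (psi_hat - naive) / naive, plus the cross-species
    mean magnitude; undefined (NaN) when a species was never detected.
    """
    if list(data.species) != list(samples.species):
        raise ValueError("detection data and samples cover different species")
    naive = naive_occupancy(data)
    psi_hat = samples.stacked("psi_bar").mean(axis=0)
    bias = np.where(naive.to_numpy() > 0, 100.0 * (psi_hat - naive.to_numpy()) / naive.to_numpy(), np.nan)
    df = pd.DataFrame(
        {"species": data.species, "naive": naive.to_numpy(), "psi_hat": psi_hat, "bias_pct": bias}
    )
    df.attrs["mean_abs_bias_pct"] = float(np.nanmean(np.abs(bias)))
    return df
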