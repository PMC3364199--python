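import numpy as np
import pandas as pd
import pytest

from commoccu import (
    CommunityModelSpec,
    DetectionDataset,
    McmcConfig,
    candidate_set_size,
    gelman_rubin,
    inclusion_probabilities,
    model_averaged_summary,
    naive_bias_report,
    posterior_model_table,
    predict_marginal_occurrence,
    run_mcmc,
)
from .conftest import make_cov_table

QUICK = McmcConfig(n_chains=2, n_iter=200, n_burnin=100, thin=2, seed=5)


@pytest.fixture(scope="module")
def quick_fit():
    """One small selection run shared by the summary-level tests."""
    rng = np.random.default_rng(12)
    n, j = 3, 40
    cov = make_cov_table(rng, j, ["a", "b"])
    x = cov.matrix(["a"])[:, 0]
    psi = 1 / (1 + np.exp(-(0.3 + 1.5 * x)))
    z = (rng.random((n, j)) < psi[None, :]).astype(int)
    k = np.full(j, 10)
    y = rng.binomial(k[None, :], 0.4) * z
    y[:, 0] = np.maximum(y[:, 0], 1)  # closure
    data = DetectionDataset(
        [f"sp{i}" for i in range(n)], [f"S{s}" for s in range(j)], y, k,
        np.zeros((j, 4), int), cov.coords,
    )
    spec = CommunityModelSpec(occ_covariates=["a", "b"], det_covariates=["season"])
    cfg = McmcConfig(n_chains=2, n_iter=300, n_burnin=150, thin=3, seed=42)
    samples = run_mcmc(data, cov, spec, cfg, selection=True)
    return data, samples


class TestRunMcmc:
    def test_retained_draw_counts(self):
        # the survey protocol: 3 chains x 50,000 iterations thinned by 50
        cfg = McmcConfig(n_chains=3, n_iter=50_000, n_burnin=50_000, thin=50)
        assert cfg.draws_per_chain == 1000
        assert cfg.total_retained_draws == 3000

    def test_draw_array_shapes(self, quick_fit):
        _, s = quick_fit
        assert s.arrays["phi"].shape == (2, 100, 3)
        assert s.arrays["alpha"].shape == (2, 100, 3, 2)
        assert s.arrays["w_occ"].shape == (2, 100, 2)
        assert s.n_chains * s.n_draws == 200

    def test_same_seed_bit_identical(self, tiny_dataset):
        a = run_mcmc(tiny_dataset, None, CommunityModelSpec(), QUICK)
        b = run_mcmc(tiny_dataset, None, CommunityModelSpec(), QUICK)
        for key in a.arrays:
            np.testing.assert_array_equal(a.arrays[key], b.arrays[key])

    def test_different_seeds_agree_within_mc_error(self, tiny_dataset):
        fixed = dict(mu_phi=0.0, sigma_phi=1.0, mu_eta=0.0, sigma_eta=1.0, rho=0.0)
        spec = CommunityModelSpec(fixed_hyperparams=fixed)
        cfg1 = McmcConfig(n_chains=2, n_iter=4000, n_burnin=500, thin=2, seed=1)
        cfg2 = McmcConfig(n_chains=2, n_iter=4000, n_burnin=500, thin=2, seed=2)
        a = run_mcmc(tiny_dataset, None, spec, cfg1)
        b = run_mcmc(tiny_dataset, None, spec, cfg2)
        for key in ("psi_bar", "p_bar"):
            da, db = a.stacked(key).mean(0), b.stacked(key).mean(0)
            np.testing.assert_allclose(da, db, atol=0.03)

    def test_acceptance_rates_reported(self, quick_fit):
        _, s = quick_fit
        assert "phi" in s.accept_rates
        assert all(0.0 < r < 1.0 for r in s.accept_rates.values())


class TestAutologisticFit:
    def test_fit_with_spatial_term(self):
        # generate spatially autocorrelated occurrence and fit with the
        # auto-logistic term switched on and selectable
        from commoccu import GeneratorConfig, generate_dataset, inclusion_probabilities

        cfg = GeneratorConfig(
            n_species=3, n_sites=40, n_arrays=8, autocovariate=True,
            occ_covariates=("a",), det_covariates=("road",),
            mu_alpha=(0.8,), sigma_alpha=(0.3,), mu_beta=(0.3,), sigma_beta=(0.3,),
            mu_phi=-0.5, mu_eta=-0.5,
        )
        data, cov, truth = generate_dataset(cfg, seed=14)
        spec = CommunityModelSpec(
            occ_covariates=["a"], det_covariates=["road"],
            autocovariate=True, auto_radius_km=5.0,
        )
        mc = McmcConfig(n_chains=2, n_iter=300, n_burnin=150, thin=3, seed=6)
        s = run_mcmc(data, cov, spec, mc, selection=True)
        assert s.arrays["delta"].shape == (2, 100, 3)
        assert np.isfinite(s.stacked("mu_delta")).all()
        pr = inclusion_probabilities(s)
        assert "psi:autocov" in pr.index
        assert 0.0 <= pr["psi:autocov"] <= 1.0


class TestModelSpecSerialization:
    def test_yaml_round_trip(self, tmp_path):
        from commoccu import PriorConfig

        spec = CommunityModelSpec(
            occ_covariates=["edge", "river"], det_covariates=["road", "team"],
            autocovariate=True, auto_radius_km=4.0,
            priors=PriorConfig(mu_sd=1.5, sigma_sd=1.0, sigma_floor=0.05, w_prior=0.3),
            fixed_hyperparams={"rho": 0.2},
        )
        path = tmp_path / "model.yaml"
        spec.to_yaml(path)
        back = CommunityModelSpec.from_yaml(path)
        assert back == spec


class TestGelmanRubin:
    def test_identical_chains_near_one(self):
        # with zero between-chain variance the classic statistic gives
        # sqrt((n-1)/n), just below 1
        draws = np.sin(np.arange(50.0))
        assert gelman_rubin(np.stack([draws, draws])) == pytest.approx(1.0, abs=0.02)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 200), rng.normal(50, 1, 200)])
        assert gelman_rubin(chains) > 10.0

    def test_hand_computed_case(self):
        # chains (1,2,3) and (2,3,4): W = 1, B/n = 0.5, var+ = 2/3 + 1/2
        chains = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert gelman_rubin(chains) == pytest.approx(np.sqrt(7.0 / 6.0))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(np.ones((1, 100)))


class TestSelectionSummaries:
    def test_inclusion_requires_selection(self, tiny_dataset):
        s = run_mcmc(tiny_dataset, None, CommunityModelSpec(), QUICK, selection=False)
        with pytest.raises(ValueError, match="selection"):
            inclusion_probabilities(s)

    def test_inclusion_probabilities_in_unit_interval(self, quick_fit):
        _, s = quick_fit
        pr = inclusion_probabilities(s)
        assert list(pr.index) == ["psi:a", "psi:b", "p:season"]
        assert ((pr >= 0) & (pr <= 1)).all()

    def test_model_table_probabilities_sum_to_one(self, quick_fit):
        _, s = quick_fit
        table = posterior_model_table(s)
        assert table["posterior_probability"].sum() == pytest.approx(1.0)
        probs = table["posterior_probability"].to_numpy()
        assert (np.diff(probs) <= 1e-12).all()  # sorted descending

    def test_model_table_relative_frequency(self, quick_fit):
        _, s = quick_fit
        w, _ = s.inclusion_matrix()
        table = posterior_model_table(s)
        top = table.iloc[0]
        count = (np.asarray([''.join(map(str, row)) for row in w]) == top["pattern"]).sum()
        assert top["posterior_probability"] == pytest.approx(count / len(w))

    def test_strong_effect_attains_highest_inclusion(self):
        # planted truth: only covariate 'a' matters; across seeds its
        # posterior inclusion probability should top the candidate list
        wins = 0
        n_reps = 10
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            j = 60
            cov = make_cov_table(rng, j, ["a", "b", "c", "d", "e"])
            x = cov.matrix(["a"])[:, 0]
            psi = 1 / (1 + np.exp(-(0.0 + 2.0 * x)))
            z = (rng.random((2, j)) < psi[None, :]).astype(int)
            k = np.full(j, 12)
            y = rng.binomial(k[None, :], 0.5) * z
            y[:, 0] = np.maximum(y[:, 0], 1)
            data = DetectionDataset(
                ["s1", "s2"], [f"S{s}" for s in range(j)], y, k,
                np.zeros((j, 4), int), cov.coords,
            )
            spec = CommunityModelSpec(occ_covariates=["a", "b", "c", "d", "e"])
            cfg = McmcConfig(n_chains=2, n_iter=400, n_burnin=200, thin=2, seed=rep)
            s = run_mcmc(data, cov, spec, cfg, selection=True)
            pr = inclusion_probabilities(s)
            if pr["psi:a"] >= pr.drop("psi:a").max():
                wins += 1
        assert wins > n_reps / 2


class TestModelAveragedSummary:
    def test_point_mass_draws(self):
        # a degenerate posterior summarizes to its value with zero width
        draws = np.full((2, 50), 1.7)
        from commoccu.diagnostics import _interval

        lo, hi = _interval(draws.ravel(), 0.95)
        assert (lo, hi) == (1.7, 1.7)

    def test_quantile_convention(self):
        # equal-tailed CI of draws 1..100 under linear interpolation
        from commoccu.diagnostics import _interval

        lo, hi = _interval(np.arange(1.0, 101.0), 0.95)
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)

    def test_symmetric_draws_unflagged(self):
        from commoccu.diagnostics import _effect_flag

        rng = np.random.default_rng(8)
        assert _effect_flag(rng.normal(0, 1, 4000)) is None
        assert _effect_flag(rng.normal(5, 1, 4000)) == ("+", 95)
        assert _effect_flag(rng.normal(-5, 1, 4000)) == ("-", 95)

    def test_summary_tables_complete(self, quick_fit):
        _, s = quick_fit
        out = model_averaged_summary(s)
        assert set(out) == {"hyper", "species"}
        assert len(out["species"]) == 3
        hyper = out["hyper"].set_index("parameter")
        assert "mu_alpha[a]" in hyper.index
        incl = hyper.dropna(subset=["mean"])
        assert (incl["ci95_lo"] <= incl["mean"]).all()
        assert (incl["mean"] <= incl["ci95_hi"]).all()
        assert (incl["ci95_lo"] <= incl["ci80_lo"]).all()
        assert (incl["ci80_hi"] <= incl["ci95_hi"]).all()


class TestCandidateSetSize:
    @pytest.mark.parametrize(
        "n_occ, auto, n_det, expected",
        [
            (10, True, 6, 131_072),  # the full survey model: 2^17
            (0, False, 0, 1),
            (3, False, 0, 8),
        ],
    )
    def test_powers_of_two(self, n_occ, auto, n_det, expected):
        spec = CommunityModelSpec(
            occ_covariates=[f"o{i}" for i in range(n_occ)],
            det_covariates=[f"d{i}" for i in range(n_det)],
            autocovariate=auto,
        )
        assert candidate_set_size(spec) == expected


class TestMarginalPrediction:
    def test_monotone_when_coefficient_positive(self, quick_fit):
        _, s = quick_fit
        grid = np.linspace(-2, 2, 9)
        curve = predict_marginal_occurrence(s, "sp0", "a", grid)
        alpha = s.stacked("alpha")[:, 0, 0] * s.stacked("w_occ")[:, 0]
        if (alpha > 0).all():
            assert (np.diff(curve["psi"]) > 0).all()

    def test_at_zero_matches_intercept_mean(self, quick_fit):
        _, s = quick_fit
        curve = predict_marginal_occurrence(s, "sp0", "a", np.array([0.0]))
        phi = s.stacked("phi")[:, 0]
        assert curve["psi"].iloc[0] == pytest.approx(
            float((1 / (1 + np.exp(-phi))).mean())
        )

    def test_unknown_covariate_rejected(self, quick_fit):
        _, s = quick_fit
        with pytest.raises(KeyError, match="not in the occurrence model"):
            predict_marginal_occurrence(s, "sp0", "zzz", np.array([0.0]))


class TestNaiveBias:
    def test_zero_bias_identity_and_arithmetic(self, quick_fit):
        data, s = quick_fit
        rep = naive_bias_report(data, s)
        hand = 100.0 * (rep["psi_hat"] - rep["naive"]) / rep["naive"]
        np.testing.assert_allclose(rep["bias_pct"], hand)

    def test_printed_survey_magnitudes(self):
        # naive 0.246 vs model 0.263 is a ~7% negative bias of the naive measure
        assert 100 * (0.263 - 0.246) / 0.246 == pytest.approx(6.9, abs=0.05)
        assert 100 * (0.3 - 0.1) / 0.1 == pytest.approx(200.0)
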