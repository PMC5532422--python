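import numpy as np
import pytest

from neutroforecast import (
    IndividualMAP,
    PKConfig,
    Scenario,
    fit_individual,
    fit_scenario,
    map_objective,
    restrict_observations,
    simulate_trial,
)
from neutroforecast.population import apply_covariates
from neutroforecast.simulate import ObservationSet


@pytest.fixture(scope="module")
def small_trial(pop):
    return simulate_trial(pop, 8, seed=31, pk_config=PKConfig(exposure_scale=1.0))


@pytest.fixture(scope="module")
def noise_free_trial(pop):
    return simulate_trial(pop, 15, seed=32, sigma_log=0.0,
                          pk_config=PKConfig(exposure_scale=1.0))


class TestObjective:
    def test_matches_independent_formula_at_random_points(self, pop, small_trial):
        """Objective equals a separately coded data-plus-prior sum to 1e-10."""
        p = small_trial[0]
        obs = restrict_observations(p, Scenario("daily", 10))
        model = IndividualMAP(obs, pop, p.covariates, p.conc)
        rng = np.random.default_rng(8)
        for _ in range(20):
            eta = rng.normal(0.0, pop.omegas)
            # independent evaluation: generic ODE path + explicit sums
            f = model.predict(eta, obs.times_h)
            data = np.sum((np.log(obs.anc) - np.log(f)) ** 2) / pop.sigma_log**2
            prior = np.sum(eta**2 / pop.omegas**2)
            assert model.objective(eta) == pytest.approx(data + prior, rel=1e-10)

    def test_prior_only_at_truth_with_noise_free_data(self, pop, noise_free_trial):
        """At the generating eta with noise-free data the data term vanishes."""
        p = noise_free_trial[0]
        obs = restrict_observations(p, Scenario("daily", 21))
        val = map_objective(p.ind.eta, obs, pop, p.covariates, p.conc)
        prior = np.sum(p.ind.eta**2 / pop.omegas**2)
        assert val == pytest.approx(prior, abs=1e-6)

    def test_baseline_at_typical_value_minimised_at_zero(self, pop, small_trial):
        """A baseline observation equal to the typical ANC0 pins eta at 0."""
        p = small_trial[0]
        anc0_t, _, _ = apply_covariates(pop, p.covariates)
        obs = ObservationSet(np.array([0]), np.array([anc0_t]), "baseline_only")
        res = fit_individual(obs, pop, p.covariates, p.conc)
        np.testing.assert_allclose(res.params, 0.0, atol=1e-6)


class TestFit:
    def test_baseline_only_matches_analytic_shrinkage(self, pop, small_trial):
        """Single baseline point: eta_anc0 is the closed-form shrunken
        residual and the uninformed effects stay at the prior mode."""
        for p in small_trial[:4]:
            obs = restrict_observations(p, Scenario("baseline_only"))
            res = fit_individual(obs, pop, p.covariates, p.conc)
            anc0_t, _, _ = apply_covariates(pop, p.covariates)
            r = np.log(obs.anc[0] / anc0_t)
            w2, s2 = pop.omegas[0] ** 2, pop.sigma_log**2
            assert res.params[0] == pytest.approx(r * w2 / (w2 + s2), abs=1e-5)
            assert abs(res.params[0]) <= abs(r) + 1e-12  # shrinkage toward 0
            np.testing.assert_allclose(res.params[1:], 0.0, atol=1e-5)

    def test_recovers_eta_from_rich_noise_free_data(self, pop, noise_free_trial):
        """Noise-free daily data (sigma set to the data's noise level):
        the MAP estimate returns the generating random effects."""
        errs = []
        for p in noise_free_trial:
            obs = restrict_observations(p, Scenario("daily", 21))
            res = fit_individual(obs, pop, p.covariates, p.conc, sigma=0.05)
            errs.append(np.max(np.abs(res.params - p.ind.eta)))
        assert max(errs) < 0.02

    def test_objective_never_worse_than_prior_mode(self, pop, small_trial):
        for p in small_trial:
            obs = restrict_observations(p, Scenario("daily", 7))
            model = IndividualMAP(obs, pop, p.covariates, p.conc)
            res = model.fit()
            assert res.objective_value <= model.objective(np.zeros(3)) + 1e-9

    def test_deterministic_given_seed_and_data(self, pop, small_trial):
        p = small_trial[0]
        obs = restrict_observations(p, Scenario("daily", 7))
        a = fit_individual(obs, pop, p.covariates, p.conc, seed=4)
        b = fit_individual(obs, pop, p.covariates, p.conc, seed=4)
        np.testing.assert_array_equal(a.params, b.params)

    def test_more_data_beats_baseline_only(self, pop, small_trial):
        """Median random-effect error shrinks from baseline-only to rich
        monitoring (noisy data, so compared in the median)."""
        err = {}
        for scen in (Scenario("baseline_only"), Scenario("daily", 15)):
            fits = fit_scenario(small_trial, scen, pop)
            err[scen.name] = np.median(
                [np.abs(f.params - p.ind.eta).sum() for f, p in zip(fits, small_trial)]
            )
        assert err["daily:15"] < err["baseline_only"]

    def test_zero_iiv_component_stays_pinned(self, ref_cov, small_trial):
        from neutroforecast import PopulationModel

        pop0 = PopulationModel(iiv_cv={"anc0": 0.25, "mtt": 0.0, "slope": 0.36})
        p = small_trial[0]
        obs = restrict_observations(p, Scenario("daily", 7))
        res = fit_individual(obs, pop0, p.covariates, p.conc)
        assert res.params[1] == 0.0


class TestResults:
    def test_summary_and_uncertainty(self, pop, small_trial):
        p = small_trial[0]
        obs = restrict_observations(p, Scenario("daily", 10))
        res = fit_individual(obs, pop, p.covariates, p.conc)
        text = res.summary()
        assert "eta_anc0" in text and "converged" in text
        bse = res.bse
        assert np.all(np.isfinite(bse)) and np.all(bse > 0)
        # conditioning on data can only sharpen the prior
        assert np.all(bse <= pop.omegas + 1e-6)

    def test_forecast_error_identities(self, pop, small_trial):
        p = small_trial[0]
        obs = restrict_observations(p, Scenario("daily", 7))
        res = fit_individual(obs, pop, p.covariates, p.conc)
        day = 14.0
        err = res.forecast_error(p, day)
        pred = res.pred_traj.at_days([day])[0]
        true = p.true_traj.at_days([day])[0]
        assert err == pytest.approx(np.log(pred) - np.log(true))
        assert res.accuracy_ratio(p, day) == pytest.approx(pred / true)
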