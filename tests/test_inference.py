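import numpy as np
import pandas as pd
import pytest

import traitgrowth as tg
from traitgrowth.inference import quickfit

from conftest import FAST, TINY


def _single_species_dataset(form, params, n, sigma, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(1.0, 60.0, n)
    f = tg.evaluate_curve(form, params, x)
    h = np.exp(np.log(f) + sigma * rng.standard_normal(n))
    obs = pd.DataFrame({"species": "solo", "age": x, "height": h})
    traits = pd.DataFrame(index=pd.Index(["solo"], name="species"))
    return tg.GrowthDataset(obs, traits)


class TestQuickfit:
    @pytest.mark.parametrize(
        "form, params",
        [("NEGEXP2", [120.0, 0.15]), ("MONOD2", [150.0, 9.0]), ("HS3", [200.0, 0.4, 12.0])],
    )
    def test_recovers_noise_free_curves(self, form, params):
        rng = np.random.default_rng(0)
        x = rng.uniform(1.0, 80.0, 120)
        h = tg.evaluate_curve(form, params, x)
        beta_hat, sigma_hat = quickfit(form, x, h)
        np.testing.assert_allclose(beta_hat, params, rtol=0.02)
        assert sigma_hat < 0.01

    def test_deterministic(self):
        ds = _single_species_dataset("NEGEXP2", [80.0, 0.2], 50, 0.2, 3)
        x = ds.observations["age"]
        h = ds.observations["height"]
        a = quickfit("NEGEXP2", x, h)
        b = quickfit("NEGEXP2", x, h)
        np.testing.assert_array_equal(a[0], b[0])


class TestFit:
    def test_single_species_parameter_recovery_within_10pct(self):
        # alpha=50, beta=0.3, sigma=0.1, n=200: implied curve parameters from
        # the posterior mean must land within 10% of the generating truth
        ds = _single_species_dataset("NEGEXP2", [50.0, 0.3], 200, 0.1, 11)
        linkage = tg.build_linkage("intercept", ds, "NEGEXP2")
        settings = tg.SamplerSettings(chains=1, warmup=250, draws=250, seed=5, leapfrog_steps=32)
        draws = tg.fit(ds, "NEGEXP2", linkage, settings=settings)
        beta_draws = draws.species_beta_draws()  # (S, K, J=1)
        implied = beta_draws.mean(axis=0)[:, 0]
        assert implied[0] == pytest.approx(50.0, rel=0.10)
        assert implied[1] == pytest.approx(0.3, rel=0.10)

    def test_same_seed_same_draws(self, small_dataset):
        cfg, dataset, _ = small_dataset
        a = tg.fit(dataset, cfg.form, cfg.linkage(), settings=TINY)
        b = tg.fit(dataset, cfg.form, cfg.linkage(), settings=TINY)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_uninformed_coefficient_stays_prior_dominated(self):
        # a trait that is constant (zero) across species carries no
        # information: its coefficient's posterior spread must stay near the
        # prior scale, far wider than an informative trait's coefficient
        cfg = tg.SimulationConfig(
            form="MONOD2", n_species=5, obs_per_species=12, n_traits=1,
            gamma={"alpha": [120.0, 30.0], "beta": [6.0, 0.0]},
            tau=0.05, sigma=0.15, seed=9,
        )
        dataset, _ = tg.generate(cfg)
        traits = dataset.traits.assign(flat=0.0)
        dataset = tg.GrowthDataset(dataset.observations, traits)
        linkage = tg.build_linkage({"alpha": ["trait_1", "flat"]}, dataset, "MONOD2")
        priors = tg.PriorSpec(coef_prior_scale=20.0)
        settings = tg.SamplerSettings(chains=1, warmup=400, draws=400, seed=2, leapfrog_steps=48)
        draws = tg.fit(dataset, "MONOD2", linkage, priors, settings)
        pop = draws.population_frame()
        sd_flat = pop["gamma[alpha,flat]"].std()
        sd_info = pop["gamma[alpha,trait_1]"].std()
        assert sd_flat > 5 * sd_info
        assert sd_flat > 8.0  # at least ~40% of the prior sd (20)

    def test_all_chain_failures_surface_as_fit_error(self, small_dataset, monkeypatch):
        cfg, dataset, _ = small_dataset
        import traitgrowth.inference as inf

        def boom(*a, **k):
            raise RuntimeError("synthetic chain failure")

        monkeypatch.setattr(inf, "sample_chain", boom)
        with pytest.raises(tg.FitError):
            tg.fit(dataset, cfg.form, cfg.linkage(), settings=TINY)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    cfg, dataset, _ = small_dataset
    return dataset, tg.fit(dataset, cfg.form, cfg.linkage(), settings=FAST)


class TestPrediction:
    def test_new_species_prediction_depends_only_on_traits(self, fitted):
        dataset, draws = fitted
        ages = np.array([2.0, 10.0, 40.0])
        row = {"trait_1": 0.4, "trait_2": -1.0}
        a = tg.predict_heights(draws, row, ages, species_observed=False)
        b = tg.predict_heights(draws, dict(row), ages, species_observed=False)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.lower, b.lower)

    def test_interval_ordering_and_positivity(self, fitted):
        dataset, draws = fitted
        ages = np.linspace(1.0, 80.0, 9)
        pred = tg.predict_heights(draws, dataset.trait_row(dataset.species[0]), ages,
                                  species_observed=True, species=dataset.species[0])
        assert np.all(pred.lower <= pred.median + 1e-12)
        assert np.all(pred.median <= pred.upper + 1e-12)
        assert np.all(pred.lower > 0)

    def test_observed_species_requires_known_id(self, fitted):
        dataset, draws = fitted
        with pytest.raises(KeyError):
            tg.predict_heights(draws, {"trait_1": 0, "trait_2": 0}, [5.0],
                               species_observed=True, species="not_a_species")

    def test_nonpositive_ages_rejected(self, fitted):
        dataset, draws = fitted
        with pytest.raises(ValueError):
            tg.predict_heights(draws, {"trait_1": 0, "trait_2": 0}, [0.0])


class TestDiagnostics:
    def test_two_chain_toy_posterior_converges(self, small_dataset):
        cfg, dataset, _ = small_dataset
        settings = tg.SamplerSettings(chains=2, warmup=200, draws=200, seed=4, leapfrog_steps=32)
        draws = tg.fit(dataset, cfg.form, cfg.linkage(), settings=settings)
        diag = tg.diagnostics(draws)
        assert diag["chains"] == 2
        assert diag["max_rhat"] is not None

    def test_single_chain_flags_missing_rhat(self, small_dataset):
        cfg, dataset, _ = small_dataset
        draws = tg.fit(dataset, cfg.form, cfg.linkage(), settings=TINY)
        diag = tg.diagnostics(draws)
        assert diag["max_rhat"] is None
        assert any("single chain" in f for f in diag["flags"])
        assert not diag["ok"]

    def test_deliberately_short_run_warns(self, small_dataset):
        cfg, dataset, _ = small_dataset
        settings = tg.SamplerSettings(chains=2, warmup=20, draws=30, seed=6, leapfrog_steps=8)
        draws = tg.fit(dataset, cfg.form, cfg.linkage(), settings=settings)
        diag = tg.diagnostics(draws)
        assert diag["flags"]  # low ESS and/or high R-hat must be flagged
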