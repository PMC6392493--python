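import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import lognorm, norm

import traitgrowth as tg
from traitgrowth.model import HierarchicalGrowthModel, LatentState, ParameterLayout


def _random_state(layout, rng, scale=1.0):
    gamma, tau, z = [], [], []
    for gk in layout.group_sizes:
        gamma.append(scale * rng.normal(size=gk))
        tau.append(np.exp(rng.normal(-1.5, 0.3, size=gk)))
        z.append(rng.normal(size=(layout.n_species, gk)))
    return LatentState(tuple(gamma), tuple(tau), tuple(z), float(np.exp(rng.normal(-1.5, 0.2))))


def _valid_state(layout, rng):
    """Random state whose Monod curves stay positive for every species,
    keeping the density on the ordinary likelihood branch (no penalty)."""
    intercepts = (150.0, 8.0)
    gamma, tau, z = [], [], []
    for k, gk in enumerate(layout.group_sizes):
        g = 0.3 * intercepts[k] * 0.1 * rng.normal(size=gk)
        g[0] = intercepts[k] * (1.0 + 0.1 * rng.normal())
        gamma.append(g)
        tau.append(np.exp(rng.normal(-2.0, 0.3, size=gk)))
        z.append(0.5 * rng.normal(size=(layout.n_species, gk)))
    return LatentState(tuple(gamma), tuple(tau), tuple(z), float(np.exp(rng.normal(-1.5, 0.2))))


def naive_log_density(model, state):
    """Loop-based independent transcription of the three model layers.

    Same additive-constant conventions as the package density: the
    observation layer is fully normalized, latent-layer priors are written
    on the unconstrained scale with their log-transform Jacobians.
    """
    linkage = model.linkage
    total = 0.0
    std = model.std_traits
    species = model.species
    for _, row in model.dataset.observations.iterrows():
        j = species.index(row["species"])
        beta = []
        for k in range(linkage.n_params):
            val = 0.0
            for g, name in enumerate(linkage.per_param[k]):
                t = 1.0 if name == "intercept" else float(std.loc[row["species"], name])
                coef = state.gamma[k][g] + state.tau[k][g] * state.z[k][j, g]
                val += coef * t
            beta.append(val)
        f = float(tg.evaluate_curve(model.form, beta, row["age"]))
        if not np.isfinite(f) or f <= model.curve_floor:
            total += -model.penalty_base
            if np.isfinite(f):
                total += -model.penalty_slope * max(model.curve_floor - f, 0.0)
        else:
            total += lognorm.logpdf(row["height"], s=state.sigma, scale=f)
    c = model.priors.coef_prior_scale
    s = model.priors.sd_prior_scale
    for k in range(linkage.n_params):
        for g in range(len(linkage.per_param[k])):
            total += -state.gamma[k][g] ** 2 / (2 * c**2)
            total += -state.tau[k][g] ** 2 / (2 * s**2) + math.log(state.tau[k][g])
            for j in range(len(species)):
                total += -state.z[k][j, g] ** 2 / 2
    total += -state.sigma**2 / (2 * s**2) + math.log(state.sigma)
    return total


@pytest.fixture(scope="module")
def toy_model():
    cfg = tg.SimulationConfig(
        form="MONOD2", n_species=3, obs_per_species=6, n_traits=2,
        gamma={"alpha": [100.0, 20.0, 0.0], "beta": [5.0, 1.0, 0.0]},
        tau=0.1, sigma=0.2, seed=3,
    )
    dataset, _ = tg.generate(cfg)
    return HierarchicalGrowthModel(dataset, "MONOD2", cfg.linkage(),
                                   parameterization="noncentered")


class TestSpeciesParameters:
    def test_hand_computed_inner_product(self, small_dataset):
        _, dataset, _ = small_dataset
        linkage = tg.build_linkage({"alpha": ["trait_1"]}, dataset, "MONOD2")
        layout = ParameterLayout(linkage, dataset.n_species)
        state = LatentState(
            gamma=(np.array([2.0, 0.5]), np.array([3.0])),
            tau=(np.array([0.0, 0.0]), np.array([0.0])),
            z=(np.zeros((4, 2)), np.zeros((4, 1))),
            sigma=0.1,
        )
        beta = tg.species_parameters(state, {"trait_1": 4.0, "trait_2": 9.9}, linkage)
        assert beta[0] == pytest.approx(2.0 + 0.5 * 4.0)
        assert beta[1] == pytest.approx(3.0)

    def test_intercept_only_collapse_and_determinism(self, small_dataset):
        _, dataset, _ = small_dataset
        linkage = tg.build_linkage("intercept", dataset, "NEGEXP2")
        state = LatentState(
            gamma=(np.array([7.0]), np.array([0.4])),
            tau=(np.array([0.0]), np.array([0.0])),
            z=(np.zeros((4, 1)), np.zeros((4, 1))),
            sigma=0.1,
        )
        rows = [{"trait_1": v, "trait_2": -v} for v in (0.0, 1.7)]
        betas = [tg.species_parameters(state, r, linkage) for r in rows]
        np.testing.assert_array_equal(betas[0], betas[1])
        np.testing.assert_allclose(betas[0], [7.0, 0.4])


class TestLogDensity:
    def test_matches_loop_oracle_on_random_states(self, toy_model, rng):
        layout = toy_model.layout
        for _ in range(10):
            state = _random_state(layout, rng, scale=30.0)
            theta = layout.pack(state)
            got = toy_model.log_density(theta)
            want = naive_log_density(toy_model, state)
            assert got == pytest.approx(want, abs=1e-10 * max(1.0, abs(want)))

    def test_centered_and_noncentered_agree_up_to_jacobian(self, toy_model, rng):
        # same constrained state: densities differ by the reparameterization
        # Jacobian, -J * sum(log tau)
        cen = HierarchicalGrowthModel(
            toy_model.dataset, toy_model.form, toy_model.linkage,
            parameterization="centered",
        )
        state = _valid_state(toy_model.layout, rng)
        diff = cen.log_density(cen.layout.pack(state)) - toy_model.log_density(
            toy_model.layout.pack(state)
        )
        expected = -toy_model.layout.n_species * sum(
            float(np.sum(np.log(t))) for t in state.tau
        )
        assert diff == pytest.approx(expected, rel=1e-9)

    def test_observation_order_invariance(self, toy_model, rng):
        state = _random_state(toy_model.layout, rng, scale=30.0)
        theta = toy_model.layout.pack(state)
        shuffled = toy_model.dataset.observations.sample(frac=1.0, random_state=1)
        other = HierarchicalGrowthModel(
            tg.GrowthDataset(shuffled, toy_model.dataset.traits),
            toy_model.form, toy_model.linkage, parameterization="noncentered",
        )
        assert other.log_density(theta) == toy_model.log_density(theta)

    def test_single_observation_at_its_own_mode(self):
        obs = pd.DataFrame({"species": ["a"], "age": [4.0], "height": [50.0]})
        traits = pd.DataFrame(index=pd.Index(["a"], name="species"))
        dataset = tg.GrowthDataset(obs, traits)
        linkage = tg.build_linkage("intercept", dataset, "MONOD2")
        model = HierarchicalGrowthModel(dataset, "MONOD2", linkage)
        # pick alpha so that f(4) = 50 exactly: alpha * 4/(2+4) = 50
        sigma = 0.3
        state = LatentState(
            gamma=(np.array([75.0]), np.array([2.0])),
            tau=(np.array([1e-8]), np.array([1e-8])),
            z=(np.zeros((1, 1)), np.zeros((1, 1))),
            sigma=sigma,
        )
        lp = model.log_density(model.layout.pack(state))
        expected_obs_term = -math.log(50.0 * sigma * math.sqrt(2 * math.pi))
        prior = (
            -(75.0**2 + 2.0**2) / (2 * 100.0**2)
            - 2 * (1e-8) ** 2 / (2 * 4.0) + 2 * math.log(1e-8)
            - sigma**2 / (2 * 4.0) + math.log(sigma)
            - 2 * math.log(1e-8)  # centered Jacobian: -J*log tau per group
        )
        assert lp == pytest.approx(expected_obs_term + prior, rel=1e-9)

    def test_invalid_curve_takes_penalty_branch(self, toy_model):
        layout = toy_model.layout
        state = _random_state(layout, np.random.default_rng(0))
        # negative asymptote makes every Monod value negative
        state = LatentState(
            (np.array([-50.0, 0.0, 0.0]), state.gamma[1]),
            state.tau, state.z, state.sigma,
        )
        lp = toy_model.log_density(layout.pack(state))
        assert lp < -1e9

    def test_pooling_limit_as_tau_vanishes(self, toy_model, rng):
        # with tau ~ 0 the species deviations z no longer reach the
        # likelihood: changing z changes the density only through the z prior
        layout = toy_model.layout
        state = _valid_state(layout, rng)
        tiny = tuple(np.full_like(t, 1e-8) for t in state.tau)
        z2 = tuple(zk + rng.normal(size=zk.shape) for zk in state.z)
        s1 = LatentState(state.gamma, tiny, state.z, state.sigma)
        s2 = LatentState(state.gamma, tiny, z2, state.sigma)
        lp1 = toy_model.log_density(layout.pack(s1))
        lp2 = toy_model.log_density(layout.pack(s2))
        zprior1 = sum(-float(np.sum(zk**2)) / 2 for zk in s1.z)
        zprior2 = sum(-float(np.sum(zk**2)) / 2 for zk in s2.z)
        assert lp2 - lp1 == pytest.approx(zprior2 - zprior1, abs=1e-6)

    def test_scale_coherence_of_observation_terms(self, toy_model, rng):
        # doubling all heights and the curve (alpha) shifts the density by
        # exactly -n*log(2) (lognormal Jacobian) plus the analytic change in
        # the gamma prior
        layout = toy_model.layout
        state = _random_state(layout, rng, scale=20.0)
        state = LatentState(
            (np.abs(state.gamma[0]) + 50.0, np.abs(state.gamma[1]) + 5.0),
            (np.full(3, 1e-9), np.full(3, 1e-9)), state.z, state.sigma,
        )
        doubled = LatentState(
            (2.0 * state.gamma[0], state.gamma[1]), state.tau, state.z, state.sigma
        )
        ds2 = tg.GrowthDataset(
            toy_model.dataset.observations.assign(
                height=toy_model.dataset.observations["height"] * 2.0
            ),
            toy_model.dataset.traits,
        )
        m2 = HierarchicalGrowthModel(ds2, toy_model.form, toy_model.linkage,
                                     parameterization="noncentered")
        lp1 = toy_model.log_density(layout.pack(state))
        lp2 = m2.log_density(m2.layout.pack(doubled))
        c2 = 2 * toy_model.priors.coef_prior_scale**2
        prior_shift = float(np.sum(state.gamma[0] ** 2 - doubled.gamma[0] ** 2)) / c2
        n = toy_model.n
        assert lp2 - lp1 == pytest.approx(-n * math.log(2.0) - (-prior_shift), rel=1e-9)


class TestGradients:
    @pytest.mark.parametrize("parameterization", ["centered", "noncentered"])
    def test_gradient_matches_finite_differences(self, toy_model, parameterization, rng):
        model = HierarchicalGrowthModel(
            toy_model.dataset, toy_model.form, toy_model.linkage,
            parameterization=parameterization,
        )
        layout = model.layout
        state = _valid_state(layout, rng)
        theta = layout.pack(state)
        lp, grad = model.log_density_grad(theta)
        assert lp > -1e8  # on the ordinary likelihood branch
        assert np.isfinite(lp)
        eps = 1e-6
        for i in rng.choice(layout.n_free, size=12, replace=False):
            up, down = theta.copy(), theta.copy()
            up[i] += eps
            down[i] -= eps
            fd = (model.log_density(up) - model.log_density(down)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=5e-4, abs=5e-4)
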