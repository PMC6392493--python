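"""Model fitting by HMC, posterior prediction, and convergence diagnostics.

``fit`` assembles a :class:`~traitgrowth.model.HierarchicalGrowthModel`,
initializes each chain, and runs the HMC sampler.  Two initialization
strategies are available:

* ``"quickfit"`` (default): a deterministic pooled least-squares fit of the
  curve on log heights seeds the parameter intercepts; trait coefficients
  start near zero with small per-chain jitter.  Robust at short warmup.
* ``"prior"``: random draws from the priors, retried until the implied
  curves are valid at every observed age.

``predict_heights`` turns posterior draws into per-age predicted-height
summaries for a species.  For an *observed* species the species-specific
coefficient draws (population mean + its own deviations) are used; for an
unobserved / held-out species the population-level coefficients are used
with species deviations at zero — the prediction is a function of the
species' traits and the requested ages only, never of its heights.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import GrowthDataset, TraitScaler
from .forms import ModelForm, evaluate_curve, get_form
from .hmc import ChainResult, HMCOptions, sample_chain
from .linkage import TraitLinkage, build_linkage
from .model import HierarchicalGrowthModel, LatentState, PriorSpec

__all__ = [
    "SamplerSettings",
    "PosteriorDraws",
    "PredictionSet",
    "FitError",
    "quickfit",
    "fit",
    "predict_heights",
    "diagnostics",
]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Sampler failure, raised with whatever diagnostics are available."""


@dataclass(frozen=True)
class SamplerSettings:
    """HMC run configuration (chains x (warmup + draws) iterations)."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    leapfrog_steps: int = 64
    target_accept: float = 0.9
    step_jitter: float = 0.5
    init: str = "quickfit"  # or "prior"
    parameterization: str = "centered"  # or "noncentered"

    def hmc_options(self) -> HMCOptions:
        return HMCOptions(
            warmup=self.warmup,
            draws=self.draws,
            leapfrog_steps=self.leapfrog_steps,
            target_accept=self.target_accept,
            step_jitter=self.step_jitter,
        )


# ---------------------------------------------------------------------------
# quickfit: deterministic pooled curve fit (initializer and test oracle)
# ---------------------------------------------------------------------------


def _starting_values(form: ModelForm, x: np.ndarray, h: np.ndarray) -> list[np.ndarray]:
    hmax = float(h.max())
    xmed = float(np.median(x))
    xmax = float(x.max())
    lx = np.log(x)
    lh = np.log(h)
    a0 = 1.2 * hmax
    starts: list[list[float]] = []
    ab = form.abbreviation
    if ab == "EXP2":
        A = np.column_stack([np.ones_like(lx), lx])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        starts = [[coef[0], max(coef[1], 1e-3)], [np.median(h), hmax / max(np.log(xmax + 1), 1.0)]]
    elif ab == "KOBLOG2":
        starts = [[hmax / max(math.log1p(xmax / xmed), 0.1), xmed], [a0, 1.0]]
    elif ab == "MONOD2":
        starts = [[a0, xmed], [2.0 * hmax, xmax]]
    elif ab == "NEGEXP2":
        starts = [[a0, 1.0 / max(np.mean(x), 0.5)], [a0, 0.05]]
    elif ab == "PWR2":
        A = np.column_stack([np.ones_like(lx), lx])
        coef, *_ = np.linalg.lstsq(A, lh, rcond=None)
        starts = [[math.exp(coef[0]), coef[1]], [1.0, 1.0]]
    elif ab == "PWR3":
        A = np.column_stack([np.ones_like(lx), lx])
        coef, *_ = np.linalg.lstsq(A, lh, rcond=None)
        starts = [[math.exp(coef[0]), coef[1], 0.01], [1.0, 1.0, 0.01]]
    elif ab == "ARCH3":
        starts = [[a0, 1.0, 0.5], [2.0 * a0, 2.0, 0.8]]
    elif ab == "HS3":
        starts = [[a0, 5.0 / max(xmax - float(x.min()), 1.0), xmed], [a0, 0.3, xmed]]
    elif ab == "HSlog3":
        starts = [[a0, 1.0, float(np.median(lx))], [a0, 2.0, float(np.median(lx))]]
    elif ab == "LOG3":
        b0 = 5.0 / max(xmax, 1.0)
        starts = [[a0, b0, b0 * xmed], [a0, 0.2, 0.2 * xmed]]
    elif ab == "WEIB3":
        starts = [[a0, 1.0 / max(xmed, 0.5), 1.0], [a0, 0.05, 1.5]]
    else:  # pragma: no cover - registry is closed
        raise KeyError(ab)
    return [np.asarray(s, dtype=float) for s in starts]


def quickfit(
    form: "str | ModelForm", ages, heights
) -> tuple[np.ndarray, float]:
    """Deterministic pooled least-squares curve fit on log heights.

    Minimizes ``sum((log h - log f(x; beta))^2)`` with a quadratic penalty
    for invalid curve values, via Nelder-Mead from form-specific starting
    values.  Returns ``(beta_hat, sigma_hat)`` where ``sigma_hat`` is the
    residual sd on the log scale.  Used to initialize HMC and, in tests, as
    an independent point-estimation oracle.
    """
    form = get_form(form)
    x = np.asarray(ages, dtype=float)
    h = np.asarray(heights, dtype=float)
    lh = np.log(h)

    def objective(beta):
        f = evaluate_curve(form, beta, x)
        bad = ~np.isfinite(f) | (f <= 1e-8)
        if bad.all():
            return 1e12
        resid = np.zeros_like(f)
        good = ~bad
        resid[good] = lh[good] - np.log(f[good])
        pen = float(bad.sum()) * 1e6
        fin = np.isfinite(f) & bad
        pen += float(np.sum(np.maximum(1e-8 - f[fin], 0.0))) * 1e3
        return float(np.sum(resid**2)) + pen

    best = None
    for s0 in _starting_values(form, x, h):
        res = minimize(
            objective, s0, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    beta_hat = np.asarray(best.x, dtype=float)
    f = evaluate_curve(form, beta_hat, x)
    good = np.isfinite(f) & (f > 1e-8)
    if good.sum() >= 2:
        sigma_hat = float(np.std(lh[good] - np.log(f[good])))
    else:
        sigma_hat = 1.0
    return beta_hat, max(sigma_hat, 1e-3)


# ---------------------------------------------------------------------------
# chain initialization
# ---------------------------------------------------------------------------


def _quickfit_init(
    model: HierarchicalGrowthModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Initial unconstrained vector + per-coordinate posterior-scale guess."""
    beta_hat, sigma_hat = quickfit(model.form, model.x, model.h)
    lay = model.layout
    centered = lay.parameterization == "centered"
    gamma, tau, z = [], [], []
    scale = np.ones(lay.n_free)
    for k in range(lay.n_curve_params):
        gk = lay.group_sizes[k]
        mag = abs(beta_hat[k]) + 0.1
        g0 = np.zeros(gk)
        g0[0] = beta_hat[k]
        gamma.append(g0 + 0.05 * mag * rng.standard_normal(gk))
        tau.append(
            np.exp(math.log(0.1 * mag) + 0.1 * rng.standard_normal(gk))
        )
        z.append(0.01 * rng.standard_normal((lay.n_species, gk)))
        scale[lay.gamma_slices[k]] = 0.1 * mag
        scale[lay.log_tau_slices[k]] = 0.7
        scale[lay.z_slices[k]] = 0.1 * mag if centered else 1.0
    sigma = math.exp(math.log(max(sigma_hat, 0.05)) + 0.05 * rng.standard_normal())
    scale[lay.log_sigma_index] = 0.3
    theta = lay.pack(LatentState(tuple(gamma), tuple(tau), tuple(z), sigma))
    return theta, scale


def _prior_init(
    model: HierarchicalGrowthModel, rng: np.random.Generator, max_tries: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Random draw from the priors, retried until the log density is finite
    and no observation falls in invalid-curve territory."""
    lay = model.layout
    pr = model.priors
    centered = lay.parameterization == "centered"
    scale = np.ones(lay.n_free)
    for k in range(lay.n_curve_params):
        scale[lay.gamma_slices[k]] = pr.coef_prior_scale
        scale[lay.log_tau_slices[k]] = 0.7
        if centered:
            scale[lay.z_slices[k]] = pr.coef_prior_scale
    scale[lay.log_sigma_index] = 0.7
    best = None
    for _ in range(max_tries):
        gamma, tau, z = [], [], []
        for k in range(lay.n_curve_params):
            gk = lay.group_sizes[k]
            gamma.append(pr.coef_prior_scale * rng.standard_normal(gk))
            tau.append(np.abs(pr.sd_prior_scale * rng.standard_normal(gk)) + 1e-6)
            z.append(rng.standard_normal((lay.n_species, gk)))
        sigma = abs(pr.sd_prior_scale * rng.standard_normal()) + 1e-6
        theta = lay.pack(LatentState(tuple(gamma), tuple(tau), tuple(z), sigma))
        lp = model.log_density(theta)
        if np.isfinite(lp) and lp > -model.penalty_base / 2:
            return theta, scale
        if np.isfinite(lp) and (best is None or lp > best[0]):
            best = (lp, theta)
    if best is not None:
        logger.warning("prior initialization found no fully valid draw; using best of %d", max_tries)
        return best[1], scale
    raise FitError("could not find a finite prior initialization")


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Posterior sample plus everything needed to reuse it.

    ``draws`` holds the unconstrained parameter vectors, shape
    ``(chains, draws_per_chain, n_free)``.  The attached model carries the
    trait scaler, linkage and form so that prediction on new species applies
    the training standardization.
    """

    model: HierarchicalGrowthModel
    draws: np.ndarray
    settings: SamplerSettings
    chain_stats: list[dict] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def stacked(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def states(self) -> list[LatentState]:
        lay = self.model.layout
        return [lay.unpack(t) for t in self.stacked()]

    def population_frame(self) -> pd.DataFrame:
        """Draws of the population-level quantities, on the constrained scale."""
        lay = self.model.layout
        rows = [lay.population_values(lay.unpack(t)) for t in self.stacked()]
        return pd.DataFrame(rows, columns=lay.population_names())

    def species_beta_draws(self) -> np.ndarray:
        """(S, K, J) curve parameters per draw and species (constrained)."""
        lay = self.model.layout
        flat = self.stacked()
        out = np.empty((flat.shape[0], lay.n_curve_params, lay.n_species))
        for s, theta in enumerate(flat):
            out[s] = self.model.species_beta(lay.unpack(theta))
        return out

    def population_array(self) -> np.ndarray:
        """(chains, draws, P) constrained population-level quantities."""
        lay = self.model.layout
        C, S, _ = self.draws.shape
        out = np.empty((C, S, len(lay.population_names())))
        for c in range(C):
            for s in range(S):
                out[c, s] = lay.population_values(lay.unpack(self.draws[c, s]))
        return out

    @property
    def divergences(self) -> int:
        return sum(st.get("divergences", 0) for st in self.chain_stats)

    # -- persistence ----------------------------------------------------
    def save(self, outdir: "str | Path") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.population_frame().to_csv(outdir / "population_draws.csv", index=False)
        C, S, D = self.draws.shape
        flat = pd.DataFrame(self.stacked())
        flat.insert(0, "chain", np.repeat(np.arange(C), S))
        flat.to_csv(outdir / "unconstrained_draws.csv", index=False)
        meta = {
            "form": self.model.form.abbreviation,
            "linkage": self.model.linkage.to_dict(),
            "scaler": self.model.scaler.to_dict(),
            "settings": {
                "chains": self.settings.chains,
                "warmup": self.settings.warmup,
                "draws": self.settings.draws,
                "seed": self.settings.seed,
                "leapfrog_steps": self.settings.leapfrog_steps,
                "target_accept": self.settings.target_accept,
                "init": self.settings.init,
            },
            "chain_stats": self.chain_stats,
        }
        (outdir / "fit.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


def fit(
    dataset: GrowthDataset,
    form: "str | ModelForm",
    linkage: "TraitLinkage | str | Mapping",
    priors: PriorSpec = PriorSpec(),
    settings: SamplerSettings = SamplerSettings(),
    scaler: "TraitScaler | None" = None,
) -> PosteriorDraws:
    """Fit the hierarchical growth model by HMC.

    Reproducible under a fixed ``settings.seed``; chains run sequentially on
    independent seed streams.  Raises :class:`FitError` when every chain
    fails rather than returning an empty result.
    """
    form = get_form(form)
    if not isinstance(linkage, TraitLinkage):
        linkage = build_linkage(linkage, dataset, form)
    if dataset.n_species < 2:
        logger.warning(
            "fitting with %d species: species-level hierarchy is weakly informed",
            dataset.n_species,
        )
    model = HierarchicalGrowthModel(
        dataset, form, linkage, priors, scaler=scaler,
        parameterization=settings.parameterization,
    )
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    opts = settings.hmc_options()

    chain_draws = []
    chain_stats = []
    errors = []
    for c, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        try:
            if settings.init == "prior":
                theta0, scale = _prior_init(model, rng)
            else:
                theta0, scale = _quickfit_init(model, rng)
            result = sample_chain(model.log_density_grad, theta0, rng, opts, scale_guess=scale)
        except Exception as exc:  # noqa: BLE001 - surfaced via FitError below
            logger.warning("chain %d failed: %s", c, exc)
            errors.append(exc)
            continue
        chain_draws.append(result.draws)
        chain_stats.append(
            {
                "chain": c,
                "accept_rate": result.accept_rate,
                "divergences": result.divergences,
                "warmup_divergences": result.warmup_divergences,
                "step_size": result.step_size,
            }
        )
    if not chain_draws:
        raise FitError(f"all {settings.chains} chains failed; first error: {errors[0]!r}")
    draws = np.stack(chain_draws)
    return PosteriorDraws(model=model, draws=draws, settings=settings, chain_stats=chain_stats)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionSet:
    """Per-age posterior summaries of predicted height (cm)."""

    ages: np.ndarray
    mean: np.ndarray  # posterior mean of the predictive mean height
    median: np.ndarray  # posterior median of the median height (the curve)
    lower: np.ndarray
    upper: np.ndarray
    interval: float
    n_clamped: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages, "mean": self.mean, "median": self.median,
                "lower": self.lower, "upper": self.upper,
            }
        )


def predict_heights(
    draws: PosteriorDraws,
    traits: "Mapping[str, float] | pd.Series",
    ages,
    species_observed: bool = False,
    species: "str | None" = None,
    interval: float = 0.90,
    marginalize_new_species: bool = False,
    rng: "np.random.Generator | None" = None,
) -> PredictionSet:
    """Posterior predictive height summaries for one species.

    Parameters
    ----------
    traits
        Raw (unstandardized) trait values; the training scaler is applied.
    species_observed
        When True, ``species`` must name a training species and its own
        coefficient draws are used.  When False the species deviations are
        set to zero (predict from traits alone) unless
        ``marginalize_new_species`` draws fresh deviations per posterior
        draw (requires ``rng``).
    """
    model = draws.model
    lay = model.layout
    x = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(x <= 0):
        raise ValueError("prediction ages must be positive")
    std_row = model.scaler.transform_row(dict(traits))
    T = [model.linkage.design_row(std_row, k) for k in range(lay.n_curve_params)]

    j = None
    if species_observed:
        if species is None or species not in model.species:
            raise KeyError(f"species {species!r} was not in the training data")
        j = model.species.index(species)
    if marginalize_new_species and rng is None:
        raise ValueError("marginalize_new_species requires an rng")

    flat = draws.stacked()
    S = flat.shape[0]
    curves = np.empty((S, x.size))
    means = np.empty((S, x.size))
    n_clamped = 0
    for s in range(S):
        state = lay.unpack(flat[s])
        beta = np.empty(lay.n_curve_params)
        for k in range(lay.n_curve_params):
            if j is not None:
                coef = state.gamma[k] + state.tau[k] * state.z[k][j]
            elif marginalize_new_species:
                coef = state.gamma[k] + state.tau[k] * rng.standard_normal(len(state.tau[k]))
            else:
                coef = state.gamma[k]
            beta[k] = float(coef @ T[k])
        f = evaluate_curve(model.form, beta, x)
        bad = ~np.isfinite(f) | (f <= 0)
        if bad.any():
            n_clamped += int(bad.sum())
            f = np.where(bad, model.curve_floor, f)
        curves[s] = f
        means[s] = f * math.exp(0.5 * state.sigma**2)
    lo = (1.0 - interval) / 2.0
    return PredictionSet(
        ages=x,
        mean=means.mean(axis=0),
        median=np.median(curves, axis=0),
        lower=np.quantile(curves, lo, axis=0),
        upper=np.quantile(curves, 1.0 - lo, axis=0),
        interval=interval,
        n_clamped=n_clamped,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def diagnostics(draws: PosteriorDraws, rhat_warn: float = 1.05, ess_warn: float = 100.0) -> dict:
    """Convergence summary over population-level quantities.

    Uses rank-normalized split R-hat and bulk effective sample size (via
    arviz).  R-hat needs >= 2 chains; with a single chain it is reported as
    unavailable and flagged.
    """
    import arviz as az

    names = draws.model.layout.population_names()
    arr = draws.population_array()  # (C, S, P)
    C = arr.shape[0]
    out: dict = {
        "chains": C,
        "draws_per_chain": int(arr.shape[1]),
        "divergences": draws.divergences,
        "accept_rates": [st["accept_rate"] for st in draws.chain_stats],
    }
    per_quantity = {}
    flags = []
    if draws.divergences > 0:
        flags.append(f"{draws.divergences} divergent transitions")
    dataset = az.from_dict(posterior={name: arr[:, :, i] for i, name in enumerate(names)})
    ess = az.ess(dataset)
    if C >= 2:
        rhat = az.rhat(dataset)
        for name in names:
            per_quantity[name] = {
                "rhat": float(rhat[name].values),
                "ess_bulk": float(ess[name].values),
            }
        worst = max(v["rhat"] for v in per_quantity.values())
        out["max_rhat"] = worst
        if worst > rhat_warn:
            flags.append(f"max R-hat {worst:.3f} > {rhat_warn}")
    else:
        for name in names:
            per_quantity[name] = {"rhat": None, "ess_bulk": float(ess[name].values)}
        out["max_rhat"] = None
        flags.append("single chain: R-hat unavailable")
    min_ess = min(v["ess_bulk"] for v in per_quantity.values())
    out["min_ess_bulk"] = min_ess
    if min_ess < ess_warn:
        flags.append(f"min bulk ESS {min_ess:.0f} < {ess_warn:.0f}")
    out["per_quantity"] = per_quantity
    out["flags"] = flags
    out["ok"] = not flags
    return out
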