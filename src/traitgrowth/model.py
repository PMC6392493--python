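"""The hierarchical lognormal growth model as a differentiable log density.

Generative structure, top down, for species j = 1..J and observation i:

    H_ij ~ lognormal(mu_ij, sigma)             observation layer
    mu_ij = log f(x_ij; beta_1j, ..., beta_Kj)  curve layer (f in cm)
    beta_kj = sum_{g in G_k} gamma_kgj * t_gj   trait-regression layer
    gamma_kgj ~ N(gamma_kg, tau_kg)             species-specific coefficients

with population coefficients gamma_kg ~ N(0, c), and
half-normal(0, s) priors on every tau_kg and on sigma (defaults s = 2,
c = 100; traits are standardized, heights in cm).  The curve f models the
*median* height in cm; its log is the lognormal location, which keeps the
asymptote parameters directly interpretable on the cm scale.

Parameter combinations whose curve is non-positive (or non-finite) at an
observed age break the lognormal link; such observations contribute a large
finite penalty with a linear restoring slope instead of -inf, which keeps
HMC trajectories finite and pushes them back toward the valid region.

Two equivalent parameterizations of the species layer are available.  The
*centered* form (default) samples the species coefficients gamma_kgj
directly with prior N(gamma_kg, tau_kg); it mixes well when each species
carries enough observations to pin its own curve, which is the typical
regime for size-at-age chronosequence data.  The *non-centered* form
samples standardized deviations z_kgj with gamma_kgj = gamma_kg +
tau_kg*z_kgj, the better geometry when species are data-poor.

The unconstrained parameter vector (in packing order) is::

    gamma[k][g]  ...  log_tau[k][g]  ...  species block [k][j][g]  ...  log_sigma

where the species block holds gamma_kgj (centered) or z_kgj
(non-centered).  Gradients of the log posterior with respect to every
unconstrained coordinate are computed analytically (curve-parameter
gradients come from the form registry) and are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import GrowthDataset, TraitScaler
from .forms import ModelForm, get_form
from .linkage import TraitLinkage

__all__ = [
    "PriorSpec",
    "LatentState",
    "ParameterLayout",
    "HierarchicalGrowthModel",
    "species_parameters",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales for the hierarchical model.

    ``sd_prior_scale``: half-normal scale for sigma and every tau (prior mean
    0).  ``coef_prior_scale``: normal scale for the population-level
    coefficients gamma on standardized traits; the default 100 is weakly
    informative when heights are in cm (asymptote-scale intercepts are
    O(100)).
    """

    sd_prior_scale: float = 2.0
    coef_prior_scale: float = 100.0

    def __post_init__(self):
        if self.sd_prior_scale <= 0 or self.coef_prior_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class LatentState:
    """One point in the latent space, on the constrained scale.

    ``gamma[k]``: (G_k,) population coefficients; ``tau[k]``: (G_k,) species
    deviation sds; ``z[k]``: (J, G_k) standardized species deviations;
    ``sigma``: lognormal scale (log-cm).
    """

    gamma: tuple[np.ndarray, ...]
    tau: tuple[np.ndarray, ...]
    z: tuple[np.ndarray, ...]
    sigma: float

    def species_coefficients(self, k: int) -> np.ndarray:
        """(J, G_k) species-specific coefficients gamma_kgj."""
        return self.gamma[k][None, :] + self.tau[k][None, :] * self.z[k]


class ParameterLayout:
    """Maps between the flat unconstrained vector and a LatentState.

    The species block of the vector stores the species coefficients
    gamma_kgj themselves under the centered parameterization, or the
    standardized deviations z_kgj under the non-centered one; a
    :class:`LatentState` always exposes standardized deviations ``z``.
    """

    def __init__(self, linkage: TraitLinkage, n_species: int, parameterization: str = "centered"):
        if parameterization not in ("centered", "noncentered"):
            raise ValueError(f"unknown parameterization {parameterization!r}")
        self.parameterization = parameterization
        self.linkage = linkage
        self.n_species = n_species
        self.group_sizes = tuple(len(names) for names in linkage.per_param)
        K = len(self.group_sizes)
        pos = 0
        self.gamma_slices = []
        for gk in self.group_sizes:
            self.gamma_slices.append(slice(pos, pos + gk))
            pos += gk
        self.log_tau_slices = []
        for gk in self.group_sizes:
            self.log_tau_slices.append(slice(pos, pos + gk))
            pos += gk
        self.z_slices = []
        for gk in self.group_sizes:
            self.z_slices.append(slice(pos, pos + n_species * gk))
            pos += n_species * gk
        self.log_sigma_index = pos
        self.n_free = pos + 1
        self.n_curve_params = K

    def unpack(self, theta: np.ndarray) -> LatentState:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"expected theta of shape ({self.n_free},), got {theta.shape}")
        gamma = tuple(theta[s].copy() for s in self.gamma_slices)
        tau = tuple(np.exp(theta[s]) for s in self.log_tau_slices)
        blocks = [
            theta[s].reshape(self.n_species, gk)
            for s, gk in zip(self.z_slices, self.group_sizes)
        ]
        if self.parameterization == "centered":
            z = tuple((c - g[None, :]) / t[None, :] for c, g, t in zip(blocks, gamma, tau))
        else:
            z = tuple(blocks)
        sigma = float(np.exp(theta[self.log_sigma_index]))
        return LatentState(gamma, tau, z, sigma)

    def pack(self, state: LatentState) -> np.ndarray:
        theta = np.empty(self.n_free)
        for s, g in zip(self.gamma_slices, state.gamma):
            theta[s] = g
        for s, t in zip(self.log_tau_slices, state.tau):
            theta[s] = np.log(t)
        for k, s in enumerate(self.z_slices):
            block = (
                state.species_coefficients(k)
                if self.parameterization == "centered"
                else np.asarray(state.z[k])
            )
            theta[s] = block.ravel()
        theta[self.log_sigma_index] = math.log(state.sigma)
        return theta

    def population_names(self) -> list[str]:
        """Names of population-level quantities (gamma, tau, sigma) in order."""
        names = []
        pnames = self.linkage.form.param_names
        for k, traits in enumerate(self.linkage.per_param):
            for g in traits:
                names.append(f"gamma[{pnames[k]},{g}]")
        for k, traits in enumerate(self.linkage.per_param):
            for g in traits:
                names.append(f"tau[{pnames[k]},{g}]")
        names.append("sigma")
        return names

    def population_values(self, state: LatentState) -> np.ndarray:
        vals = [v for g in state.gamma for v in g]
        vals += [v for t in state.tau for v in t]
        vals.append(state.sigma)
        return np.array(vals)


def species_parameters(
    state: LatentState,
    std_trait_row: Mapping[str, float],
    linkage: TraitLinkage,
    species_index: "int | None" = None,
) -> np.ndarray:
    """Curve parameter vector beta for one species (Eq. 3 inner product).

    ``std_trait_row`` maps trait name to *standardized* value.  With
    ``species_index`` given, species-specific coefficients
    ``gamma + tau * z_j`` are used; otherwise population-level coefficients
    (the "typical species" — the rule for predicting unobserved species).
    """
    beta = np.empty(linkage.n_params)
    for k in range(linkage.n_params):
        t = linkage.design_row(std_trait_row, k)
        if species_index is None:
            coef = state.gamma[k]
        else:
            coef = state.gamma[k] + state.tau[k] * state.z[k][species_index]
        if coef.shape != t.shape:
            raise ValueError(
                f"coefficient/trait dimension mismatch for parameter {k}: "
                f"{coef.shape} vs {t.shape}"
            )
        beta[k] = float(coef @ t)
    return beta


class HierarchicalGrowthModel:
    """Log density (and gradient) of the full model over a dataset.

    Parameters
    ----------
    dataset, form, linkage, priors
        The data, curve form, trait linkage and prior scales.
    scaler
        Trait scaler fitted on the *training* species; fitted from
        ``dataset`` when omitted.
    penalty_base, penalty_slope
        Per-observation penalty for invalid (non-positive / non-finite)
        curve values, and the linear restoring slope on the curve deficit.
    curve_floor
        Curve values below this are treated as invalid (cm).
    """

    def __init__(
        self,
        dataset: GrowthDataset,
        form: "str | ModelForm",
        linkage: TraitLinkage,
        priors: PriorSpec = PriorSpec(),
        scaler: "TraitScaler | None" = None,
        penalty_base: float = 1e10,
        penalty_slope: float = 1e6,
        curve_floor: float = 1e-6,
        parameterization: str = "centered",
    ):
        self.form = get_form(form)
        if linkage.form.abbreviation != self.form.abbreviation:
            raise ValueError("linkage was built for a different form")
        self.dataset = dataset
        self.linkage = linkage
        self.priors = priors
        self.penalty_base = float(penalty_base)
        self.penalty_slope = float(penalty_slope)
        self.curve_floor = float(curve_floor)

        self.species = dataset.species
        J = len(self.species)
        self.scaler = scaler if scaler is not None else TraitScaler.fit(dataset.traits, self.species)
        std = self.scaler.transform(dataset.traits)
        self.std_traits = std
        self.design = [
            linkage.design_matrix(std, self.species, k) for k in range(linkage.n_params)
        ]  # each (J, G_k)
        self.layout = ParameterLayout(linkage, J, parameterization)

        # observations sorted canonically (species, age, height) so that the
        # density and every derived computation is order-invariant
        obs = dataset.observations.sort_values(
            ["species", "age", "height"], kind="mergesort"
        ).reset_index(drop=True)
        sp_index = {s: j for j, s in enumerate(self.species)}
        self.obs_species = obs["species"].map(sp_index).to_numpy(dtype=int)
        self.x = obs["age"].to_numpy(dtype=float)
        self.h = obs["height"].to_numpy(dtype=float)
        self.log_h = np.log(self.h)
        self.n = len(obs)

    # -- curve layer ----------------------------------------------------
    def species_beta(self, state: LatentState) -> np.ndarray:
        """(K, J) curve parameters for every species."""
        K = self.linkage.n_params
        J = len(self.species)
        beta = np.empty((K, J))
        for k in range(K):
            coef = state.species_coefficients(k)  # (J, G_k)
            beta[k] = np.sum(self.design[k] * coef, axis=1)
        return beta

    # -- log density ----------------------------------------------------
    def log_density(self, theta: np.ndarray) -> float:
        return self._density(np.asarray(theta, float), want_grad=False)[0]

    def log_density_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        return self._density(np.asarray(theta, float), want_grad=True)

    def _density(self, theta: np.ndarray, want_grad: bool):
        lay = self.layout
        # guard: wild leapfrog excursions can push the log-scale coordinates
        # past exp() range; treat that territory as zero-density
        if not np.all(np.isfinite(theta)):
            return -np.inf, (np.zeros(lay.n_free) if want_grad else None)
        log_scales = [theta[s] for s in lay.log_tau_slices]
        log_scales.append(theta[lay.log_sigma_index : lay.log_sigma_index + 1])
        if max(float(np.max(np.abs(v))) for v in log_scales) > 300.0:
            return -np.inf, (np.zeros(lay.n_free) if want_grad else None)
        state = lay.unpack(theta)
        beta = self.species_beta(state)  # (K, J)
        beta_obs = beta[:, self.obs_species]  # (K, n)
        from .forms import curve_with_gradient

        f, grads = curve_with_gradient(self.form, tuple(beta_obs), self.x)
        f = np.asarray(f, dtype=float)
        sigma = state.sigma
        floor = self.curve_floor

        valid = np.isfinite(f) & (f > floor)
        n_valid = int(valid.sum())
        logp = 0.0
        dldf = np.zeros(self.n) if want_grad else None

        if n_valid:
            mu = np.log(f[valid])
            resid = self.log_h[valid] - mu
            logp += float(
                -np.sum(self.log_h[valid])
                - n_valid * (math.log(sigma) + 0.5 * _LOG_2PI)
                - np.sum(resid**2) / (2.0 * sigma**2)
            )
            if want_grad:
                dldf[valid] = (resid / sigma**2) / f[valid]
        n_invalid = self.n - n_valid
        if n_invalid:
            inval = ~valid
            deficit = np.where(
                np.isfinite(f[inval]), np.maximum(floor - f[inval], 0.0), 1.0
            )
            logp += -self.penalty_base * n_invalid - self.penalty_slope * float(deficit.sum())
            if want_grad:
                push = np.zeros(inval.sum())
                fin = np.isfinite(f[inval])
                push[fin] = self.penalty_slope  # d logp / d f = +slope while f < floor
                dldf[inval] = push

        # -- priors (on the unconstrained scale, with Jacobians) --------
        c2 = self.priors.coef_prior_scale**2
        s2 = self.priors.sd_prior_scale**2
        centered = lay.parameterization == "centered"
        for k in range(lay.n_curve_params):
            logp += float(-np.sum(state.gamma[k] ** 2) / (2.0 * c2))
            # half-normal on tau with log-transform Jacobian (log tau = theta)
            logp += float(-np.sum(state.tau[k] ** 2) / (2.0 * s2) + np.sum(theta[lay.log_tau_slices[k]]))
            # species layer: N(gamma, tau) on the coefficients; expressed via
            # z = (coef - gamma)/tau this is -z^2/2 (+ -log tau per coordinate
            # under the centered parameterization, where coef is the free
            # coordinate)
            logp += float(-np.sum(state.z[k] ** 2) / 2.0)
            if centered:
                logp += -lay.n_species * float(np.sum(theta[lay.log_tau_slices[k]]))
        logp += -(sigma**2) / (2.0 * s2) + float(theta[lay.log_sigma_index])

        if not want_grad:
            return (logp if np.isfinite(logp) else -np.inf), None

        # -- gradient ----------------------------------------------------
        grad = np.zeros(lay.n_free)
        resid_full = np.zeros(self.n)
        if n_valid:
            resid_full[valid] = self.log_h[valid] - np.log(f[valid])

        for k in range(lay.n_curve_params):
            with np.errstate(all="ignore"):
                dldbeta_obs = dldf * np.asarray(grads[k], dtype=float)  # (n,)
            dldbeta_obs = np.where(np.isfinite(dldbeta_obs), dldbeta_obs, 0.0)
            dldbeta = np.bincount(
                self.obs_species, weights=dldbeta_obs, minlength=len(self.species)
            )  # (J,)
            T = self.design[k]  # (J, G_k)
            tau_k = state.tau[k]
            z_k = state.z[k]
            if centered:
                # free species block holds the coefficients c = gamma + tau*z
                dc = dldbeta[:, None] * T - z_k / tau_k[None, :]
                grad[lay.z_slices[k]] = dc.ravel()
                grad[lay.gamma_slices[k]] = np.sum(z_k, axis=0) / tau_k - state.gamma[k] / c2
                grad[lay.log_tau_slices[k]] = (
                    np.sum(z_k**2 - 1.0, axis=0) - tau_k**2 / s2 + 1.0
                )
            else:
                grad[lay.gamma_slices[k]] = T.T @ dldbeta - state.gamma[k] / c2
                dz = (dldbeta[:, None] * T) * tau_k[None, :] - z_k
                grad[lay.z_slices[k]] = dz.ravel()
                dtau = np.sum((dldbeta[:, None] * T) * z_k, axis=0)  # d/d tau (likelihood)
                grad[lay.log_tau_slices[k]] = tau_k * dtau - tau_k**2 / s2 + 1.0
        # log sigma
        dlogsigma = 0.0
        if n_valid:
            dlogsigma += float(-n_valid + np.sum(resid_full[valid] ** 2) / sigma**2)
        dlogsigma += -(sigma**2) / s2 + 1.0
        grad[lay.log_sigma_index] = dlogsigma

        if not np.isfinite(logp):
            return -np.inf, np.zeros(lay.n_free)
        grad = np.where(np.isfinite(grad), grad, 0.0)
        return logp, grad

    # -- convenience ----------------------------------------------------
    def curve_values(self, state: LatentState) -> np.ndarray:
        """f(x_ij; beta_j) for every observation (model-implied median, cm)."""
        beta = self.species_beta(state)[:, self.obs_species]
        from .forms import curve_with_gradient

        f, _ = curve_with_gradient(self.form, tuple(beta), self.x)
        return np.asarray(f, dtype=float)
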