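# Methods

## Model

The observation layer is lognormal: `H_ij ~ lognormal(mu_ij, sigma)` with a
single shared scale `sigma` (log-cm).  Heights are strictly positive and
right-skewed, and a multiplicative error model means absolute error grows
with height, which matches how measurement and micro-site variation behave
in size-at-age field data.  A per-species `sigma_j` is not fitted by
default: with tens of observations per species it is weakly identified and
it complicates pooled evaluation.

The location is `mu_ij = log f(x_ij; beta_j)`: the curve `f` models the
**median** height in cm, so bounded-form asymptotes (`alpha`) read directly
as maximum attainable heights on the scale the categorization thresholds
use.  The posterior-predictive mean height is `f * exp(sigma^2 / 2)`; both
mean and median are reported, and the mean is the default point prediction
for metric computation.

Each curve parameter is a linear (identity-link) function of standardized
traits with species-specific coefficients:

    beta_kj   = sum_{g in G_k} gamma_kgj * t_gj
    gamma_kgj ~ Normal(gamma_kg, tau_kg)

Traits are centered and scaled to unit sd across the *training* species;
the scaler is persisted and applied to held-out species at prediction time,
and is refit on every cross-validation training fold so no information
about the held-out species leaks through the standardization.

An identity link can produce parameter combinations whose curve is zero or
negative at an observed age, where the lognormal link is undefined.  Such
observations contribute a large finite penalty (−1e10 each) plus a linear
restoring term (slope 1e6 per cm of curve deficit) instead of −infinity;
trajectories that graze the invalid region are rejected by the sampler's
energy check while still feeling a gradient back toward validity.  Both
constants are configurable on `HierarchicalGrowthModel`.

### Curve forms

Eleven forms are registered (six concave, five sigmoidal; seven with a
finite asymptote).  Three printed equations in the source literature for
this family are typographically ambiguous; the registry fixes one canonical
algebraic reading per form and documents it in the module docstring:

* Archibald: `alpha / (beta + omega^x)` with `0 < omega < 1`, the reading
  consistent with a bounded sigmoidal classification (asymptote
  `alpha/beta`, not `alpha`);
* 3-parameter logistic: `alpha / (1 + exp(-beta*x + omega))`;
* extended power: `alpha * x^beta - omega/x`.

Every reading is pinned by tests against independently written sympy
transcriptions (values to 1e-12, parameter gradients against symbolic
derivatives).  Forms containing `log(x)` or `1/x` reject age zero;
datasets require strictly positive ages anyway, since chronosequence ages
are elapsed times since a disturbance.

## Priors

* `sigma`, every `tau_kg`: half-normal(0, 2) — weakly informative on the
  log-cm / coefficient-deviation scales.
* population coefficients `gamma_kg`: normal(0, 100).  Heights are in cm,
  so asymptote-scale intercepts are O(100); a much tighter default would
  visibly shrink them.  Configurable via `PriorSpec(coef_prior_scale=...)`;
  on standardized traits a smaller scale (10–20) is a reasonable choice
  when all curve parameters are O(1–10).

## Inference

Sampling is Hamiltonian Monte Carlo implemented in the package
(`traitgrowth.hmc`): leapfrog integration with analytic gradients of the
full log posterior, dual-averaging step-size adaptation toward 0.9
acceptance, windowed diagonal-metric adaptation regularized toward a
per-coordinate scale guess, trajectory-length jitter (±50% around the
`leapfrog_steps` setting) to avoid periodic behavior, and an energy-error
divergence check at 1000.  Defaults: 4 chains × (1000 warmup + 1000 draws),
64 leapfrog steps; chains run sequentially on independent seed streams, so
results are bit-reproducible for a fixed seed.

**Parameterization.**  The species layer is *centered* by default: the
species coefficients `gamma_kgj` are sampled directly with their
`N(gamma_kg, tau_kg)` prior.  With 15–30 observations per species the data
pin each species' curve, and the non-centered form (`gamma + tau*z`) then
couples the population mean to all species deviations through a narrow
ridge that a diagonal-metric sampler traverses very slowly.  The
non-centered form remains available (`parameterization="noncentered"`) and
is the better geometry for very data-sparse species.  Both forms are
checked against the same loop-based density oracle and against each other
(they differ by exactly the `-J*sum(log tau)` reparameterization Jacobian).

**Initialization.**  Default is a deterministic "quickfit": a pooled
Nelder-Mead least-squares fit of the curve on log heights (multi-start,
form-specific starting heuristics) seeds the parameter intercepts, trait
coefficients start near zero, and each chain adds small jitter.  Drawing
initial values from the priors (`init="prior"`, with retries until the
implied curves are valid) is also supported; at short warmup budgets it is
markedly less reliable because cm-scale prior draws usually start in
invalid-curve territory.  Quickfit also serves as an independent point
-estimation oracle in the tests.

**Diagnostics.**  Rank-normalized split R-hat and bulk ESS (via arviz) over
the population-level quantities, divergence and acceptance-rate counters,
and an overall ok/warn flag.  R-hat needs ≥ 2 chains and is flagged as
unavailable otherwise.

**Prediction for unobserved species** uses population-level coefficients
with species deviations at zero — the "typical species with these traits"
prediction, and the stricter test of whether traits carry the information.
Optionally deviations can be marginalized by drawing fresh `z` per
posterior draw (`marginalize_new_species=True`), which widens intervals but
leaves point predictions nearly unchanged.

## Evaluation

* **naive**: one fit on all data; every observation predicted with its own
  species' coefficient draws.
* **cv_species**: J refits, fold `f` seeded `base_seed + 1 + f`, each
  excluding one species' heights; pooled predicted-vs-observed pairs across
  folds (every observation predicted exactly once).  Per-species metric
  breakdowns are available as diagnostics.

Metrics: Pearson r², RMSD, MD, and the exact decomposition
`MSD = SB + SDSD + LCS` (`MSV = SDSD + LCS`) using population (1/n)
standard deviations so the identity holds to machine precision.  Undefined
r² (zero-variance predictions) is reported as NaN and categorized "bad" /
"incomparable".

Categorization thresholds (cm): naive r² 0.75/0.40/0.10, RMSD 50/100/200,
|MD| 10/30/100; CV r² 0.40/0.20/0.10, RMSD 100/200/500, |MD| 50/100/500.
Boundary convention: for r² the better category is inclusive of its cut
(`>= 0.75` is good); for RMSD/|MD| the better category is exclusive
(`< 50` is good, `50 <= v < 100` adequate).  MD is categorized on its
absolute value — bias counts in either direction — while the signed value
is always reported.  The sensitivity harness multiplies the cm cuts by a
factor (e.g. 2 and 0.5); r² cuts are proportions, not cm, and are left
unscaled.  Consensus over the three metrics: majority category, or the
middle category (under good < adequate < poor < bad) when all three differ.

## Synthetic data

The generator runs the model forward: traits ~ N(0,1) per species, species
coefficients `gamma + tau*z`, ages uniform on [1, 86] years (the span of a
long fire-chronosequence record), lognormal heights.  Species whose
realized parameters fail the positivity screen anywhere on the age range
are redrawn (up to 1000 retries; the count is recorded).  Per-species
observation counts can be fixed or drawn from a range to mimic unbalanced
field sampling.

What the generator does *not* emulate: site-clustered ages (real
chronosequences sample a few discrete sites), trait measurement error and
trait covariance, site covariates, survival/detection filtering.  Passing
tests therefore demonstrate correctness of the machinery and behavior of
the estimators *when the model is true*, not robustness to the
mis-specification real field data would add.

Two study designs are used by the tests and the acceptance script, with
scales chosen to be realistic for shrub/small-tree height data (asymptotes
100–300 cm, growth rates 0.2–0.6 per year, half-height ages 5–25 years,
15–20% lognormal noise):

* **recovery**: hillslope curves, 12 species × 30 observations, two traits,
  `tau = 0.1`, `sigma = 0.15`, truth `alpha = (180, 40, -30)`,
  rate `= (0.5, 0.1, 0)`, half-height age `= (12, 3, 0)`.  The rate
  intercept is set high enough that species-level deviations cannot push
  growth rates negative — shrinking plants have unidentifiable asymptotes
  and are not a regime these data exhibit.
* **overfit demo** (`overfit_demo_config`): 8 species × 15 observations,
  hillslope, both trait coefficients zero, large between-species spread
  (asymptote 200 ± 80 cm).  A global-linkage fit looks good in-sample and
  cannot predict held-out species, producing a naive-minus-CV r² gap well
  above 0.3.

The recovery report maps posterior coefficient draws back to the
generator's raw trait scale (undoing the per-fit standardization) before
comparing with truth.

## Numerical choices and limitations

* Observations are sorted canonically (species, age, height) inside the
  model, so densities, fits and reports are invariant to input row order
  and to fold processing order.
* Reduced sampling profiles (1–2 chains × 150–300 iterations, 32–96
  leapfrog steps) are used for the test-suite and acceptance studies; they
  pass recovery and calibration checks at those sizes but real analyses
  should use the defaults and check diagnostics.
* ESS on hierarchical scale parameters (`tau`) is the weakest link at short
  warmup; posterior means of population coefficients are much better
  behaved than interval endpoints for `tau`.
* `compare_models` isolates failures per cell and never writes non-finite
  values without an `incomparable`/`failed` status flag.
* Information criteria (AIC/DIC/WAIC) are intentionally out of scope: the
  package's premise is that absolute, task-aligned predictive checks are
  the informative comparison.
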