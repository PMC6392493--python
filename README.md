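# traitgrowth

Trait-based, hierarchical non-linear growth modeling with honest predictive
evaluation.

Ecologists who need growth trajectories for many plant species — for example
to plan fire-management intervals from how fast vegetation regains height
after a burn — rarely have enough height-at-age data for every species.
Species-level *functional traits* (seed mass, stem density, leaf traits) are
far easier to obtain, so a natural strategy is to model growth-curve
parameters as functions of traits and predict curves for species that were
never measured.  This package implements that strategy end to end, and —
just as importantly — implements the evaluation machinery that reveals when
such a model merely memorizes its training species instead of learning a
transferable trait–growth relationship.

## The model

Heights `H_ij` (cm) of individual `i` of species `j` at age `x_ij` (years,
e.g. time since disturbance) follow a hierarchical lognormal model:

    H_ij  ~ lognormal(log f(x_ij; beta_j), sigma)
    beta_kj = sum_{g in G_k} gamma_kgj * t_gj          (intercept: t = 1)
    gamma_kgj ~ Normal(gamma_kg, tau_kg)

where `f` is one of **eleven curve forms** — concave or sigmoidal, bounded
(finite asymptote, interpretable as maximum height) or unbounded — from the
2-parameter Monod, negative-exponential, power and log forms up to
3-parameter hillslope (logistic in age or log-age), Weibull, Archibald,
extended-power and logistic forms (`traitgrowth forms` lists them).  Each
curve parameter `beta_k` is a linear function of a configurable set `G_k` of
standardized traits, with species-specific coefficients drawn around
population-level ones.  Priors: half-normal(0, 2) on `sigma` and every
`tau`; normal(0, 100) on population coefficients.  Fitting is Hamiltonian
Monte Carlo with analytic gradients (see `docs/methods.md`).

Two evaluation protocols produce observed-vs-predicted pairs:

* **naive** (in-sample) — fit on all data, predict every observation;
* **leave-one-species-out CV** — refit without one species' heights and
  predict that species *from its traits alone*; repeat for every species.

Pairs are scored with r², RMSD (accuracy, cm) and MD (bias, cm; positive =
over-prediction), the exact deviance decomposition
`MSD = SB + SDSD + LCS`, cm-denominated threshold categories
(good/adequate/poor/bad, stricter for naive than for CV), and a
majority-or-middle consensus across the three metrics.

## Worked example

```python
import traitgrowth as tg

config = tg.SimulationConfig(
    form="MONOD2", n_species=6, obs_per_species=20, n_traits=1,
    gamma={"alpha": [150.0, 40.0], "beta": [8.0, 0.0]},
    tau=0.05, sigma=0.15, seed=42,
)
dataset, truth = tg.generate(config)
print(dataset.summary())

settings = tg.SamplerSettings(chains=2, warmup=300, draws=300, seed=1)
naive_run, draws = tg.naive_evaluate(dataset, "MONOD2", "global", settings=settings)
cv_run = tg.cross_validate_by_species(dataset, "MONOD2", "global", settings=settings)

for run in (naive_run, cv_run):
    report = tg.evaluate_run(run)
    s = report.suite
    print(f"{run.mode:11s} r2={s.r2:.3f} rmsd={s.rmsd:.1f}cm md={s.md:+.1f}cm "
          f"-> {report.consensus}")
```

prints

```
6 species, 120 observations (per-species 20-20), traits: trait_1
naive       r2=0.770 rmsd=17.9cm md=-0.3cm -> good
cv_species  r2=0.759 rmsd=18.4cm md=+1.0cm -> good
```

Here the single trait genuinely drives the asymptote (`alpha = 150 + 40 *
trait`), so held-out species are predictable from traits: CV performance
(r² 0.76, RMSD 18 cm) nearly matches the in-sample fit and both earn a
"good" consensus under the CV-appropriate thresholds.  Had the traits been
noise, the naive fit would stay high while CV r² collapsed — that contrast
is exactly what the evaluation layer is designed to expose (the
`tg.overfit_demo_config()` preset reproduces it).  Recovery of the
generating coefficients can be checked with
`tg.recovery_report(truth, draws)`.

The same workflow is available from the shell:

```sh
traitgrowth simulate --form MONOD2 --species 6 --obs 20 --traits 1 --seed 42 --out sim/
traitgrowth validate --obs sim/observations.csv --traits sim/traits.csv \
    --form MONOD2 --linkage global --mode both --seed 1 --out val/
traitgrowth compare --obs sim/observations.csv --traits sim/traits.csv \
    --forms HS3,NEGEXP2,MONOD2 --linkage global,intercept --out cmp/
```

Observation CSVs need `species, age, height` columns (cm and years; other
names via `--column-map`); the trait CSV one row per species.  Every command
writes a `manifest.json` so runs can be reproduced byte-for-byte.

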