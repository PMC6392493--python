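"""Naive (in-sample) evaluation, leave-one-species-out cross-validation,
and the multi-form comparison harness.

Two evaluation protocols produce observed-vs-predicted height pairs:

* **naive** — one model trained on all data; each observation is predicted
  at its own age using its species' fitted coefficients.  This measures
  in-sample fit.
* **cv_species** — J refits, each excluding one species' heights; the
  held-out species is then predicted *from its traits and ages alone*
  (population-level coefficients, species deviations at zero), and the
  pairs are pooled over all species.  This measures whether the trait
  layer can transfer growth curves to an unobserved species — a stratified,
  deliberately harsh form of cross-validation.

Trait standardization is refit on each training fold so no information
about the held-out species' traits leaks into the scaling.  Fold ``f`` uses
seed ``base_seed + 1 + f`` so folds are independent of processing order and
of each other.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import GrowthDataset, TraitScaler
from .forms import get_form
from .inference import (
    FitError,
    PosteriorDraws,
    SamplerSettings,
    fit,
    predict_heights,
)
from .linkage import TraitLinkage, build_linkage
from .metrics import (
    DEFAULT_THRESHOLDS,
    MetricSuite,
    PerformanceCategory,
    ThresholdTable,
    categorize,
    consensus,
    msd_decomposition,
)
from .model import PriorSpec

__all__ = [
    "ValidationRun",
    "EvaluationReport",
    "naive_evaluate",
    "cross_validate_by_species",
    "evaluate_run",
    "compare_models",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("r2", "rmsd", "md")


@dataclass(frozen=True)
class ValidationRun:
    """Observed/predicted height pairs from one evaluation protocol.

    ``pairs`` has columns ``species, age, observed, predicted`` sorted by
    (species, age, observed) — the canonical order, independent of input
    observation order and of fold processing order.
    """

    mode: str  # "naive" | "cv_species"
    pairs: pd.DataFrame
    form_abbrev: str
    linkage: TraitLinkage
    seed: int

    @property
    def observed(self) -> np.ndarray:
        return self.pairs["observed"].to_numpy()

    @property
    def predicted(self) -> np.ndarray:
        return self.pairs["predicted"].to_numpy()

    def metrics(self) -> MetricSuite:
        return msd_decomposition(self.observed, self.predicted)

    def per_species_metrics(self) -> pd.DataFrame:
        rows = []
        for sp, grp in self.pairs.groupby("species"):
            if len(grp) < 2:
                continue
            suite = msd_decomposition(grp["observed"], grp["predicted"])
            rows.append({"species": sp, **suite.as_dict()})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EvaluationReport:
    """Raw metric values + categories + consensus for one (form, mode)."""

    mode: str
    suite: MetricSuite
    categories: Mapping[str, PerformanceCategory]
    consensus: PerformanceCategory

    @classmethod
    def from_run(
        cls, run: ValidationRun, thresholds: ThresholdTable = DEFAULT_THRESHOLDS
    ) -> "EvaluationReport":
        mode = "naive" if run.mode == "naive" else "cv"
        suite = run.metrics()
        values = {"r2": suite.r2, "rmsd": suite.rmsd, "md": suite.md}
        cats = {m: categorize(m, mode, values[m], thresholds) for m in METRIC_NAMES}
        return cls(mode=mode, suite=suite, categories=cats,
                   consensus=consensus(list(cats.values())))


evaluate_run = EvaluationReport.from_run


def _canonical(pairs: pd.DataFrame) -> pd.DataFrame:
    return pairs.sort_values(
        ["species", "age", "observed"], kind="mergesort"
    ).reset_index(drop=True)


def naive_evaluate(
    dataset: GrowthDataset,
    form,
    linkage: "TraitLinkage | str | Mapping",
    priors: PriorSpec = PriorSpec(),
    settings: SamplerSettings = SamplerSettings(),
) -> tuple[ValidationRun, PosteriorDraws]:
    """Fit on all data; predict every observation with its species' draws."""
    form = get_form(form)
    if not isinstance(linkage, TraitLinkage):
        linkage = build_linkage(linkage, dataset, form)
    draws = fit(dataset, form, linkage, priors, settings)
    rows = []
    for sp in dataset.species:
        obs = dataset.observations_for(sp)
        ages = obs["age"].to_numpy()
        pred = predict_heights(
            draws, dataset.trait_row(sp), ages, species_observed=True, species=sp
        )
        rows.append(
            pd.DataFrame(
                {"species": sp, "age": ages,
                 "observed": obs["height"].to_numpy(), "predicted": pred.mean}
            )
        )
    pairs = _canonical(pd.concat(rows, ignore_index=True))
    run = ValidationRun("naive", pairs, form.abbreviation, linkage, settings.seed)
    return run, draws


def cross_validate_by_species(
    dataset: GrowthDataset,
    form,
    linkage: "TraitLinkage | str | Mapping",
    priors: PriorSpec = PriorSpec(),
    settings: SamplerSettings = SamplerSettings(),
) -> ValidationRun:
    """Leave-one-species-out CV: J refits, pooled predicted-vs-observed pairs.

    Every observation is predicted exactly once, by a model that never saw
    its species' heights.  The held-out prediction is a pure function of
    the species' trait row, its observed ages, and the training fold.
    """
    form = get_form(form)
    if not isinstance(linkage, TraitLinkage):
        linkage = build_linkage(linkage, dataset, form)
    if dataset.n_species < 2:
        raise ValueError("cross-validation by species requires >= 2 species")
    rows = []
    for f, sp in enumerate(dataset.species):
        training = dataset.drop_species(sp)
        fold_scaler = TraitScaler.fit(training.traits, training.species)
        if fold_scaler.degenerate:
            logger.warning(
                "fold %d (held-out %s): traits %s lose their variance in training",
                f, sp, fold_scaler.degenerate,
            )
        fold_settings = dataclasses.replace(settings, seed=settings.seed + 1 + f)
        draws = fit(training, form, linkage, priors, fold_settings, scaler=fold_scaler)
        obs = dataset.observations_for(sp)
        ages = obs["age"].to_numpy()
        pred = predict_heights(
            draws, dataset.trait_row(sp), ages, species_observed=False
        )
        rows.append(
            pd.DataFrame(
                {"species": sp, "age": ages,
                 "observed": obs["height"].to_numpy(), "predicted": pred.mean}
            )
        )
    pairs = _canonical(pd.concat(rows, ignore_index=True))
    if len(pairs) != dataset.n_obs:
        raise AssertionError("pooled CV pairs must cover every observation exactly once")
    return ValidationRun("cv_species", pairs, form.abbreviation, linkage, settings.seed)


def compare_models(
    dataset: GrowthDataset,
    forms: Sequence,
    linkages: "Mapping[str, TraitLinkage | str | Mapping]",
    modes: Sequence[str] = ("naive", "cv"),
    priors: PriorSpec = PriorSpec(),
    settings: SamplerSettings = SamplerSettings(),
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    dataset_name: str = "dataset",
) -> pd.DataFrame:
    """Run every form x linkage x mode cell; one tidy row per metric.

    Output columns: dataset, form, linkage, mode, metric, value, category,
    consensus, status.  A cell whose sampler fails is marked ``failed`` (and
    the run continues); a metric whose value is non-finite or undefined is
    marked ``incomparable`` and categorized ``bad``.
    """
    if not forms:
        raise ValueError("need at least one form")
    records = []
    for form_spec in forms:
        form = get_form(form_spec)
        for lname, lspec in linkages.items():
            for mode in modes:
                try:
                    linkage = (
                        lspec if isinstance(lspec, TraitLinkage)
                        else build_linkage(lspec, dataset, form)
                    )
                    if mode == "naive":
                        run, _ = naive_evaluate(dataset, form, linkage, priors, settings)
                    elif mode in ("cv", "cv_species"):
                        run = cross_validate_by_species(dataset, form, linkage, priors, settings)
                    else:
                        raise ValueError(f"unknown mode {mode!r}")
                    report = EvaluationReport.from_run(run, thresholds)
                except (FitError, RuntimeError, np.linalg.LinAlgError) as exc:
                    logger.warning("%s/%s/%s failed: %s", form.abbreviation, lname, mode, exc)
                    for metric in METRIC_NAMES:
                        records.append(
                            {"dataset": dataset_name, "form": form.abbreviation,
                             "linkage": lname, "mode": mode, "metric": metric,
                             "value": math.nan, "category": "bad",
                             "consensus": "bad", "status": "failed"}
                        )
                    continue
                values = {"r2": report.suite.r2, "rmsd": report.suite.rmsd, "md": report.suite.md}
                for metric in METRIC_NAMES:
                    v = values[metric]
                    status = "ok" if math.isfinite(v) else "incomparable"
                    records.append(
                        {"dataset": dataset_name, "form": form.abbreviation,
                         "linkage": lname, "mode": mode, "metric": metric,
                         "value": v, "category": str(report.categories[metric]),
                         "consensus": str(report.consensus), "status": status}
                    )
    return pd.DataFrame.from_records(records)
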