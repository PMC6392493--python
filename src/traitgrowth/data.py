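"""Size-at-age observations joined to a species-level trait table.

A :class:`GrowthDataset` holds individual observations (species, age in
years, size in cm) — typically collected over a chronosequence of
time-since-disturbance sites — together with one numeric trait row per
species (seed mass, stem density, leaf traits, ...).  Sizes and ages must be
strictly positive (the observation model is lognormal and several curve
forms contain log(age)); every observed species must have a complete trait
row.

Traits are standardized (mean 0, sd 1 across the *training* species) before
entering the model; the :class:`TraitScaler` persists the centering so that
held-out or new species can be projected onto the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GrowthDataset", "TraitScaler", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

OBS_COLUMNS = ("species", "age", "height")


@dataclass(frozen=True)
class GrowthDataset:
    """Validated observations + trait table.

    Parameters
    ----------
    observations
        DataFrame with columns ``species`` (str), ``age`` (years, > 0) and
        ``height`` (cm, > 0).
    traits
        DataFrame indexed by species id with numeric trait columns (raw,
        unstandardized scale).  May contain species without observations
        (e.g. prediction targets); every observed species must be present.
    """

    observations: pd.DataFrame
    traits: pd.DataFrame

    def __post_init__(self):
        obs = self.observations
        missing = [c for c in OBS_COLUMNS if c not in obs.columns]
        if missing:
            raise ValueError(f"observations missing columns: {missing}")
        if len(obs) == 0:
            raise ValueError("empty observation table")
        obs = obs.loc[:, list(OBS_COLUMNS)].reset_index(drop=True)
        obs = obs.astype({"species": str, "age": float, "height": float})
        if (obs["age"] <= 0).any():
            raise ValueError("all ages must be strictly positive (years)")
        if (obs["height"] <= 0).any():
            raise ValueError("all heights must be strictly positive (cm): lognormal support")
        traits = self.traits.copy()
        traits.index = traits.index.astype(str)
        if traits.isna().any().any():
            raise ValueError("trait table contains missing values")
        observed = set(obs["species"])
        absent = sorted(observed - set(traits.index))
        if absent:
            raise ValueError(f"species missing from trait table: {absent}")
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "traits", traits)

    # -- basic views ----------------------------------------------------
    @property
    def species(self) -> tuple[str, ...]:
        """Observed species ids, sorted (the canonical species order)."""
        return tuple(sorted(set(self.observations["species"])))

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(self.traits.columns)

    def trait_row(self, species: str) -> pd.Series:
        if species not in self.traits.index:
            raise KeyError(f"species {species!r} has no trait row")
        return self.traits.loc[species]

    def observations_for(self, species: str) -> pd.DataFrame:
        return self.observations[self.observations["species"] == species]

    # -- fold construction ---------------------------------------------
    def drop_species(self, species: str) -> "GrowthDataset":
        """Training set for one leave-one-species-out fold.

        The species' observations are removed; its trait row is kept in the
        trait table (traits are known for the prediction target, heights are
        not) but does not influence anything fitted from observations.
        """
        if species not in self.species:
            raise KeyError(f"{species!r} is not an observed species")
        if self.n_species < 2:
            raise ValueError("cannot drop the only observed species")
        obs = self.observations[self.observations["species"] != species]
        return GrowthDataset(obs.reset_index(drop=True), self.traits)

    def summary(self) -> str:
        counts = self.observations["species"].value_counts()
        return (
            f"{self.n_species} species, {self.n_obs} observations "
            f"(per-species {counts.min()}-{counts.max()}), "
            f"traits: {', '.join(self.trait_names) or '(none)'}"
        )


@dataclass(frozen=True)
class TraitScaler:
    """Per-trait centering/scaling fitted on the training species.

    Traits with zero variance across the training species are flagged
    (``degenerate``) and passed through uncentered with unit scale — a fold
    that loses a trait's variance cannot inform that trait's effect.
    """

    mean: Mapping[str, float]
    scale: Mapping[str, float]
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def fit(cls, traits: pd.DataFrame, species: Sequence[str]) -> "TraitScaler":
        sub = traits.loc[list(species)]
        mean, scale, degenerate = {}, {}, []
        for name in traits.columns:
            col = sub[name].to_numpy(dtype=float)
            sd = float(col.std(ddof=0))
            if sd == 0.0:
                degenerate.append(name)
                mean[name] = 0.0
                scale[name] = 1.0
            else:
                mean[name] = float(col.mean())
                scale[name] = sd
        if degenerate:
            logger.warning("traits with zero variance on training species: %s", degenerate)
        return cls(dict(mean), dict(scale), tuple(degenerate))

    def transform(self, traits: pd.DataFrame) -> pd.DataFrame:
        out = traits.copy()
        for name in traits.columns:
            if name in self.mean:
                out[name] = (traits[name] - self.mean[name]) / self.scale[name]
        return out

    def transform_row(self, row: Mapping[str, float]) -> dict[str, float]:
        return {
            name: (float(row[name]) - self.mean[name]) / self.scale[name]
            for name in self.mean
        }

    def to_dict(self) -> dict:
        return {
            "mean": dict(self.mean),
            "scale": dict(self.scale),
            "degenerate": list(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TraitScaler":
        return cls(dict(d["mean"]), dict(d["scale"]), tuple(d.get("degenerate", ())))


def read_dataset(
    obs_path: "str | Path",
    traits_path: "str | Path",
    column_map: Mapping[str, str] | None = None,
) -> GrowthDataset:
    """Read observations and traits from two CSV files.

    ``column_map`` renames source columns to the canonical ``species``,
    ``age``, ``height`` names (e.g. ``{"time_since_fire": "age"}``).  Rows
    with non-positive age or height are dropped with a logged count; a
    species observed but absent from the trait table is an error.
    """
    obs = pd.read_csv(obs_path)
    if len(obs) == 0:
        raise ValueError(f"empty observation file: {obs_path}")
    if column_map:
        obs = obs.rename(columns=dict(column_map))
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"{obs_path}: missing columns {missing} (use a column map?)")
    obs = obs.loc[:, list(OBS_COLUMNS)]
    obs = obs.astype({"species": str, "age": float, "height": float})
    keep = (obs["age"] > 0) & (obs["height"] > 0) & obs["age"].notna() & obs["height"].notna()
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d rows with non-positive age or height", dropped)
    obs = obs[keep].reset_index(drop=True)
    if len(obs) == 0:
        raise ValueError(f"{obs_path}: no rows with positive age and height")

    traits = pd.read_csv(traits_path)
    if "species" not in traits.columns:
        raise ValueError(f"{traits_path}: traits CSV needs a 'species' column")
    traits = traits.set_index("species")
    return GrowthDataset(obs, traits)


def write_dataset(dataset: GrowthDataset, obs_path: "str | Path", traits_path: "str | Path") -> None:
    """Write a dataset back to the two-CSV layout consumed by read_dataset."""
    dataset.observations.to_csv(obs_path, index=False)
    dataset.traits.rename_axis("species").to_csv(traits_path)
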