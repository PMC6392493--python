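"""Trait linkage: which species-level traits feed which curve parameter.

Each curve parameter ``k`` (alpha, beta, and for 3-parameter forms omega) is
modeled as a linear combination of a chosen set of traits plus an intercept:

    beta_k,j = sum_{g in G_k} gamma_k,g,j * t_g,j        (t_intercept = 1)

The sets ``G_k`` may differ between parameters.  Two conventional choices are
the *global* linkage (every trait on every parameter — no variable selection)
and a *specific* linkage (an ecologically chosen subset per parameter, e.g.
seed mass on early growth rate, stem density on the asymptote).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import GrowthDataset
from .forms import ModelForm, get_form

__all__ = ["TraitLinkage", "build_linkage", "INTERCEPT"]

INTERCEPT = "intercept"


@dataclass(frozen=True)
class TraitLinkage:
    """Per-parameter ordered trait sets; the intercept is always first."""

    form_abbrev: str
    per_param: tuple[tuple[str, ...], ...]  # each starts with INTERCEPT

    def __post_init__(self):
        form = get_form(self.form_abbrev)
        if len(self.per_param) != form.n_params:
            raise ValueError(
                f"linkage has {len(self.per_param)} parameter entries; "
                f"{form.abbreviation} has {form.n_params} parameters"
            )
        fixed = []
        for names in self.per_param:
            rest = [n for n in names if n != INTERCEPT]
            if len(set(rest)) != len(rest):
                raise ValueError(f"duplicate trait in linkage entry: {names}")
            fixed.append((INTERCEPT, *rest))
        object.__setattr__(self, "per_param", tuple(fixed))

    @property
    def form(self) -> ModelForm:
        return get_form(self.form_abbrev)

    @property
    def n_params(self) -> int:
        return len(self.per_param)

    def traits_for(self, k: int) -> tuple[str, ...]:
        return self.per_param[k]

    def design_matrix(self, std_traits: pd.DataFrame, species: Sequence[str], k: int) -> np.ndarray:
        """(J, |G_k|) design matrix over species; first column is ones."""
        names = self.per_param[k]
        cols = [np.ones(len(species))]
        sub = std_traits.loc[list(species)]
        for name in names[1:]:
            cols.append(sub[name].to_numpy(dtype=float))
        return np.column_stack(cols)

    def design_row(self, std_trait_row: Mapping[str, float], k: int) -> np.ndarray:
        names = self.per_param[k]
        return np.array([1.0, *(float(std_trait_row[n]) for n in names[1:])])

    def to_dict(self) -> dict[str, list[str]]:
        form = self.form
        return {
            form.param_names[k]: [n for n in names if n != INTERCEPT]
            for k, names in enumerate(self.per_param)
        }


def build_linkage(
    spec: "Mapping[str | int, Sequence[str] | str] | str",
    dataset: GrowthDataset,
    form: "str | ModelForm",
) -> TraitLinkage:
    """Construct and validate a trait linkage against a dataset.

    ``spec`` may be:

    * the string ``"global"`` (or ``"all"``): every trait on every parameter;
    * the string ``"intercept"`` (or ``"none"``): intercept-only, no traits;
    * a mapping from parameter name (``"alpha"``/``"beta"``/``"omega"``) or
      0-based index to a list of trait names (or the string ``"all"``).
      Parameters not mentioned get intercept-only.

    Unknown trait names raise; the intercept term is implied everywhere.
    """
    form = get_form(form)
    if dataset.n_obs == 0:  # GrowthDataset already forbids this; belt and braces
        raise ValueError("empty dataset")
    available = set(dataset.trait_names)

    if isinstance(spec, str):
        key = spec.lower()
        if key in ("global", "all"):
            per = tuple((INTERCEPT, *dataset.trait_names) for _ in range(form.n_params))
            return TraitLinkage(form.abbreviation, per)
        if key in ("intercept", "none", "intercept_only"):
            per = tuple((INTERCEPT,) for _ in range(form.n_params))
            return TraitLinkage(form.abbreviation, per)
        raise ValueError(f"unknown linkage spec string {spec!r}")

    name_to_k = {name: k for k, name in enumerate(form.param_names)}
    per: list[tuple[str, ...]] = [(INTERCEPT,) for _ in range(form.n_params)]
    for key, traits in spec.items():
        if isinstance(key, int):
            k = key
            if not 0 <= k < form.n_params:
                raise ValueError(f"parameter index {k} out of range for {form.abbreviation}")
        else:
            if key not in name_to_k:
                raise ValueError(
                    f"unknown parameter {key!r} for {form.abbreviation}; "
                    f"expected one of {form.param_names}"
                )
            k = name_to_k[key]
        if isinstance(traits, str):
            if traits.lower() == "all":
                names = list(dataset.trait_names)
            else:
                names = [traits]
        else:
            names = list(traits)
        unknown = sorted(set(names) - available - {INTERCEPT})
        if unknown:
            raise ValueError(f"unknown trait name(s) {unknown}; dataset has {sorted(available)}")
        per[k] = (INTERCEPT, *[n for n in names if n != INTERCEPT])
    return TraitLinkage(form.abbreviation, tuple(per))
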