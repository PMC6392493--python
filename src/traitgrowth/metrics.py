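"""Model-evaluation statistics and their threshold-based categorization.

Three headline statistics compare observed sizes ``x_i`` with model
predictions ``y_i`` (both cm):

* ``r2`` — squared Pearson correlation, the proportion of variation explained;
* ``RMSD`` — root mean squared deviance, sqrt(mean((y-x)^2)), accuracy;
* ``MD`` — mean deviance, mean(y-x), bias (positive = over-prediction).

The mean squared deviance additionally decomposes exactly as

    MSD = SB + SDSD + LCS

with SB the squared bias ``(ybar-xbar)^2``, SDSD the squared difference of
(population) standard deviations, and LCS the lack of positive correlation
weighted by the standard deviations, ``2*sd_y*sd_x*(1-r)``.  MSV = SDSD+LCS is
the deviance not attributable to bias.  Population (1/n) standard deviations
make the identity exact.

Raw values are mapped to four ordered performance categories (good <
adequate < poor < bad) via cm-denominated thresholds that differ between
naive (in-sample) and leave-one-species-out cross-validated evaluation, and a
per-model consensus is formed across the three metrics by majority, falling
back to the middle category when all three disagree.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MetricSuite",
    "PerformanceCategory",
    "ThresholdTable",
    "pearson_r2",
    "rmsd",
    "md",
    "msd_decomposition",
    "metric_suite",
    "categorize",
    "consensus",
    "scale_thresholds",
]


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"observed and predicted must be 1-d and equal length; got {x.shape} vs {y.shape}"
        )
    return x, y


def pearson_r2(observed, predicted) -> float:
    """Squared Pearson correlation of observed vs predicted.

    Returns ``nan`` (an undefined value, categorized as "bad"/incomparable
    downstream) when either vector has zero variance.
    """
    x, y = _pair(observed, predicted)
    if x.size < 2:
        raise ValueError("pearson_r2 requires at least 2 pairs")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    return r * r


def rmsd(observed, predicted) -> float:
    """Root mean squared deviance, cm; lower is more accurate."""
    x, y = _pair(observed, predicted)
    if x.size < 1:
        raise ValueError("rmsd requires at least 1 pair")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def md(observed, predicted) -> float:
    """Mean deviance (bias), cm; positive values indicate over-prediction."""
    x, y = _pair(observed, predicted)
    if x.size < 1:
        raise ValueError("md requires at least 1 pair")
    return float(np.mean(y - x))


@dataclass(frozen=True)
class MetricSuite:
    """All evaluation statistics for one observed/predicted pairing."""

    n: int
    r2: float  # nan when undefined (zero-variance input)
    r: float
    rmsd: float
    md: float
    msd: float
    sb: float
    sdsd: float
    lcs: float
    msv: float
    sd_meas: float
    sd_sim: float

    @property
    def r2_defined(self) -> bool:
        return not math.isnan(self.r2)

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "r2": self.r2, "r": self.r, "rmsd": self.rmsd,
            "md": self.md, "msd": self.msd, "sb": self.sb, "sdsd": self.sdsd,
            "lcs": self.lcs, "msv": self.msv,
            "sd_meas": self.sd_meas, "sd_sim": self.sd_sim,
        }


def msd_decomposition(observed, predicted) -> MetricSuite:
    """Compute the full metric suite including the exact MSD decomposition."""
    x, y = _pair(observed, predicted)
    if x.size < 2:
        raise ValueError("msd_decomposition requires at least 2 pairs")
    sd_meas = float(x.std())  # population (1/n) convention: identity is exact
    sd_sim = float(y.std())
    bias = float(y.mean() - x.mean())
    sb = bias * bias
    sdsd = (sd_sim - sd_meas) ** 2
    if sd_meas > 0.0 and sd_sim > 0.0:
        r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sd_meas * sd_sim))
        r = max(-1.0, min(1.0, r))
        r2 = r * r
    else:
        r = math.nan
        r2 = math.nan
    lcs = max(2.0 * sd_sim * sd_meas * (1.0 - r), 0.0) if not math.isnan(r) else 0.0
    msd = sb + sdsd + lcs
    return MetricSuite(
        n=int(x.size), r2=r2, r=r, rmsd=float(np.sqrt(np.mean((y - x) ** 2))),
        md=bias, msd=msd, sb=sb, sdsd=sdsd, lcs=lcs, msv=sdsd + lcs,
        sd_meas=sd_meas, sd_sim=sd_sim,
    )


metric_suite = msd_decomposition  # alias: the suite is the decomposition


class PerformanceCategory(enum.IntEnum):
    """Ordered performance categories, best (good) to worst (bad)."""

    good = 0
    adequate = 1
    poor = 2
    bad = 3

    def __str__(self) -> str:
        return self.name


# Default thresholds (heights in cm). For r2 a *larger* value is better and
# cut points are read downward: value >= cuts[0] -> good, >= cuts[1] ->
# adequate, >= cuts[2] -> poor, else bad. For RMSD and |MD| a *smaller* value
# is better: value < cuts[0] -> good, < cuts[1] -> adequate, < cuts[2] ->
# poor, else bad. MD is categorized on its absolute value (bias counts in
# either direction); the signed value is still reported.
_DEFAULT_CUTS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("r2", "naive"): (0.75, 0.40, 0.10),
    ("rmsd", "naive"): (50.0, 100.0, 200.0),
    ("md", "naive"): (10.0, 30.0, 100.0),
    ("r2", "cv"): (0.40, 0.20, 0.10),
    ("rmsd", "cv"): (100.0, 200.0, 500.0),
    ("md", "cv"): (50.0, 100.0, 500.0),
}

_HIGHER_IS_BETTER = {"r2"}
_ABSOLUTE_VALUE = {"md"}


@dataclass(frozen=True)
class ThresholdTable:
    """Category boundaries per (metric, mode); defaults are the cm-scale table."""

    cuts: Mapping[tuple[str, str], tuple[float, float, float]] = None  # type: ignore[assignment]

    def __post_init__(self):
        cuts = dict(_DEFAULT_CUTS) if self.cuts is None else dict(self.cuts)
        for key, c in cuts.items():
            if len(c) != 3:
                raise ValueError(f"need 3 cut points for {key}, got {c}")
            metric = key[0]
            ordered = sorted(c, reverse=metric in _HIGHER_IS_BETTER)
            if tuple(ordered) != tuple(c) or len(set(c)) != 3:
                raise ValueError(f"cut points for {key} must be strictly ordered: {c}")
            cuts[key] = tuple(float(v) for v in c)
        object.__setattr__(self, "cuts", cuts)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict[str, list[float]]:
        return {f"{m}_{mode}": list(c) for (m, mode), c in self.cuts.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[float]]) -> "ThresholdTable":
        cuts = {}
        for key, c in d.items():
            metric, _, mode = key.rpartition("_")
            cuts[(metric, mode)] = tuple(float(v) for v in c)
        return cls(cuts)


DEFAULT_THRESHOLDS = ThresholdTable()


def categorize(
    metric: str,
    mode: str,
    value: float,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
) -> PerformanceCategory:
    """Map a raw metric value to a performance category.

    Boundary convention (upper categories claim their boundary): for r2,
    ``value >= cut`` reaches the better category; for RMSD/|MD|,
    ``value < cut`` does.  Undefined (nan) or infinite values map to ``bad``
    (the "incomparable" cells of a comparison table).
    """
    key = (metric, mode)
    if key not in thresholds.cuts:
        raise KeyError(f"no thresholds for metric={metric!r}, mode={mode!r}")
    v = float(value)
    if not math.isfinite(v):
        return PerformanceCategory.bad
    if metric in _ABSOLUTE_VALUE:
        v = abs(v)
    c0, c1, c2 = thresholds.cuts[key]
    if metric in _HIGHER_IS_BETTER:
        if v >= c0:
            return PerformanceCategory.good
        if v >= c1:
            return PerformanceCategory.adequate
        if v >= c2:
            return PerformanceCategory.poor
        return PerformanceCategory.bad
    if v < c0:
        return PerformanceCategory.good
    if v < c1:
        return PerformanceCategory.adequate
    if v < c2:
        return PerformanceCategory.poor
    return PerformanceCategory.bad


def consensus(categories: Sequence[PerformanceCategory]) -> PerformanceCategory:
    """Overall category from exactly three per-metric categories.

    Majority rules when two or three agree; when all three differ the middle
    category under the good < adequate < poor < bad order is taken.
    """
    cats = [PerformanceCategory(c) for c in categories]
    if len(cats) != 3:
        raise ValueError(f"consensus takes exactly 3 categories, got {len(cats)}")
    counts = Counter(cats)
    top, n = counts.most_common(1)[0]
    if n >= 2:
        return top
    return sorted(cats)[1]


def scale_thresholds(thresholds: ThresholdTable, factor: float) -> ThresholdTable:
    """Multiply the cm-denominated (RMSD, MD) cut points by ``factor``.

    The r2 cut points are proportions, not cm, and are left unchanged.  Used
    for the doubling/halving sensitivity analysis of the category assignments.
    """
    if not factor > 0:
        raise ValueError("factor must be positive")
    cuts = {
        key: (c if key[0] in _HIGHER_IS_BETTER else tuple(v * factor for v in c))
        for key, c in thresholds.cuts.items()
    }
    return ThresholdTable(cuts)
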