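"""Registry of the eleven non-linear height-vs-age curve forms.

Each form maps an age ``x`` (years) and a parameter vector to an expected
size (height, cm).  Forms carry shape metadata — concave vs sigmoidal, and
whether they possess a finite asymptote (bounded) — because bounded forms
admit a direct reading of ``alpha`` as a maximum attainable height.

Parameter conventions (``alpha``, ``beta``, ``omega``):

======== ======================== =============================================
abbrev   equation                 positive-growth regime
======== ======================== =============================================
EXP2     a + b*log(x)             b > 0 (and a large enough that f > 0 on range)
KOBLOG2  a*log(1 + x/b)           a > 0, b > 0
MONOD2   a*x/(b + x)              a > 0, b > 0
NEGEXP2  a*(1 - exp(-b*x))        a > 0, b > 0
PWR2     a*x**b                   a > 0, b > 0
PWR3     a*x**b - w/x             a > 0, b > 0, w >= 0 small (f > 0 on range)
ARCH3    a/(b + w**x)             a > 0, b > 0, 0 < w < 1  (asymptote a/b)
HS3      a/(1+exp(-b*(x-w)))      a > 0, b > 0  (half height at x = w)
HSlog3   a/(1+exp(-b*(log x -w))) a > 0, b > 0  (half height at x = exp(w))
LOG3     a/(1+exp(-b*x+w))        a > 0, b > 0  (half height at x = w/b)
WEIB3    a*(1 - exp(-b*x**w))     a > 0, b > 0, w > 0
======== ======================== =============================================

These algebraic readings are fixed here once; an independent transcription of
each equation backs them in the test suite.  Forms containing ``log(x)`` or
``1/x`` (EXP2, HSlog3, PWR3) reject age 0; all others accept age >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelForm",
    "CurveDomainError",
    "CurveValidity",
    "list_forms",
    "get_form",
    "evaluate_curve",
    "curve_with_gradient",
    "check_curve_validity",
]


class CurveDomainError(ValueError):
    """Raised when ages lie outside a form's domain (e.g. log of age 0)."""


@dataclass(frozen=True)
class ModelForm:
    """Descriptor of one parametric growth-curve form."""

    name: str
    abbreviation: str
    n_params: int
    shape_class: str  # "concave" | "sigmoidal"
    boundedness: str  # "bounded" | "unbounded"
    requires_positive_age: bool
    equation: str
    _fn: Callable = field(repr=False, compare=False)
    _grad: Callable = field(repr=False, compare=False)

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("alpha", "beta", "omega")[: self.n_params]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.abbreviation} ({self.name}): {self.equation}"


# ---------------------------------------------------------------------------
# curve functions and their parameter gradients
#
# Every function accepts broadcastable arrays for x and each parameter and is
# evaluated under errstate(all="ignore"): out-of-regime parameter values may
# yield nan/inf, which callers treat as invalid-curve territory.
# ---------------------------------------------------------------------------


def _exp2(x, a, b):
    return a + b * np.log(x)


def _exp2_grad(x, a, b):
    lx = np.log(x)
    one = np.ones(np.broadcast_shapes(np.shape(x), np.shape(a), np.shape(b)))
    return one, np.broadcast_to(lx, one.shape).copy()


def _koblog2(x, a, b):
    return a * np.log1p(x / b)


def _koblog2_grad(x, a, b):
    fa = np.log1p(x / b)
    fb = -a * x / (b * b + b * x)
    return np.broadcast_arrays(fa, fb)


def _monod2(x, a, b):
    return a * x / (b + x)


def _monod2_grad(x, a, b):
    d = b + x
    fa = x / d
    fb = -a * x / (d * d)
    return np.broadcast_arrays(fa, fb)


def _negexp2(x, a, b):
    return a * -np.expm1(-b * x)


def _negexp2_grad(x, a, b):
    e = np.exp(-b * x)
    fa = 1.0 - e
    fb = a * x * e
    return np.broadcast_arrays(fa, fb)


def _pwr2(x, a, b):
    return a * x**b


def _pwr2_grad(x, a, b):
    xb = x**b
    fa = xb
    fb = a * xb * np.log(x)
    return np.broadcast_arrays(fa, fb)


def _pwr3(x, a, b, w):
    return a * x**b - w / x


def _pwr3_grad(x, a, b, w):
    xb = x**b
    fa = xb
    fb = a * xb * np.log(x)
    fw = -1.0 / x
    return np.broadcast_arrays(fa, fb, fw)


def _arch3(x, a, b, w):
    # w**x via exp(x*log w); w <= 0 yields nan (invalid regime)
    u = np.exp(x * np.log(w))
    return a / (b + u)


def _arch3_grad(x, a, b, w):
    u = np.exp(x * np.log(w))
    d = b + u
    fa = 1.0 / d
    fb = -a / (d * d)
    fw = -a * x * np.exp((x - 1.0) * np.log(w)) / (d * d)
    return np.broadcast_arrays(fa, fb, fw)


def _hs3(x, a, b, w):
    return a * expit(b * (x - w))


def _hs3_grad(x, a, b, w):
    s = expit(b * (x - w))
    s1 = s * (1.0 - s)
    fa = s
    fb = a * s1 * (x - w)
    fw = -a * s1 * b
    return np.broadcast_arrays(fa, fb, fw)


def _hslog3(x, a, b, w):
    return a * expit(b * (np.log(x) - w))


def _hslog3_grad(x, a, b, w):
    lx = np.log(x)
    s = expit(b * (lx - w))
    s1 = s * (1.0 - s)
    fa = s
    fb = a * s1 * (lx - w)
    fw = -a * s1 * b
    return np.broadcast_arrays(fa, fb, fw)


def _log3(x, a, b, w):
    return a * expit(b * x - w)


def _log3_grad(x, a, b, w):
    s = expit(b * x - w)
    s1 = s * (1.0 - s)
    fa = s
    fb = a * s1 * x
    fw = -a * s1
    return np.broadcast_arrays(fa, fb, fw)


def _weib3(x, a, b, w):
    return a * -np.expm1(-b * x**w)


def _weib3_grad(x, a, b, w):
    u = x**w
    e = np.exp(-b * u)
    fa = 1.0 - e
    fb = a * u * e
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.log(x)
        fw = a * b * u * lx * e
    # x == 0 with w > 0: u = 0, d u/dw = 0, so fw -> 0 (lx is -inf there)
    fw = np.where(np.broadcast_to(u, np.shape(fw)) == 0.0, 0.0, fw)
    return np.broadcast_arrays(fa, fb, fw)


_REGISTRY: dict[str, ModelForm] = {}


def _register(name, abbrev, n_params, shape, bound, pos_age, equation, fn, grad):
    form = ModelForm(name, abbrev, n_params, shape, bound, pos_age, equation, fn, grad)
    _REGISTRY[abbrev.upper()] = form
    return form


_register("Exponential", "EXP2", 2, "concave", "unbounded", True,
          "alpha + beta*log(x)", _exp2, _exp2_grad)
_register("Kobayashi logarithmic", "KOBLOG2", 2, "concave", "unbounded", False,
          "alpha*log(1 + x/beta)", _koblog2, _koblog2_grad)
_register("Monod", "MONOD2", 2, "concave", "bounded", False,
          "alpha*x/(beta + x)", _monod2, _monod2_grad)
_register("Negative exponential", "NEGEXP2", 2, "concave", "bounded", False,
          "alpha*(1 - exp(-beta*x))", _negexp2, _negexp2_grad)
_register("Power", "PWR2", 2, "concave", "unbounded", False,
          "alpha*x**beta", _pwr2, _pwr2_grad)
_register("Extended power", "PWR3", 3, "concave", "unbounded", True,
          "alpha*x**beta - omega/x", _pwr3, _pwr3_grad)
_register("Archibald", "ARCH3", 3, "sigmoidal", "bounded", False,
          "alpha/(beta + omega**x)", _arch3, _arch3_grad)
_register("Hillslope", "HS3", 3, "sigmoidal", "bounded", False,
          "alpha/(1 + exp(-beta*(x - omega)))", _hs3, _hs3_grad)
_register("Hillslope log", "HSlog3", 3, "sigmoidal", "bounded", True,
          "alpha/(1 + exp(-beta*(log(x) - omega)))", _hslog3, _hslog3_grad)
_register("Logistic", "LOG3", 3, "sigmoidal", "bounded", False,
          "alpha/(1 + exp(-beta*x + omega))", _log3, _log3_grad)
_register("Cumulative Weibull", "WEIB3", 3, "sigmoidal", "bounded", False,
          "alpha*(1 - exp(-beta*x**omega))", _weib3, _weib3_grad)


def list_forms() -> tuple[ModelForm, ...]:
    """All eleven registered forms, in stable (registration) order."""
    return tuple(_REGISTRY.values())


def get_form(form: "str | ModelForm") -> ModelForm:
    """Resolve a form by abbreviation (case-insensitive) or pass one through."""
    if isinstance(form, ModelForm):
        return form
    key = str(form).upper()
    if key not in _REGISTRY:
        known = ", ".join(_REGISTRY)
        raise KeyError(f"unknown growth-model form {form!r}; known forms: {known}")
    return _REGISTRY[key]


def _check_domain(form: ModelForm, x: np.ndarray) -> None:
    if np.any(x < 0):
        raise CurveDomainError(f"{form.abbreviation}: negative ages are not allowed")
    if form.requires_positive_age and np.any(x == 0):
        raise CurveDomainError(
            f"{form.abbreviation} contains log(x) or 1/x and requires age > 0"
        )


def _check_params(form: ModelForm, params: Sequence[float]) -> np.ndarray:
    p = np.asarray(params, dtype=float)
    if p.ndim != 1 or p.shape[0] != form.n_params:
        raise ValueError(
            f"{form.abbreviation} takes {form.n_params} parameters "
            f"({', '.join(form.param_names)}); got shape {p.shape}"
        )
    return p


def evaluate_curve(form: "str | ModelForm", params: Sequence[float], age) -> np.ndarray:
    """Evaluate f(age; params) for one form.

    Parameters
    ----------
    form
        Form descriptor or abbreviation (e.g. ``"HS3"``).
    params
        Length-``n_params`` vector ``(alpha, beta[, omega])``.
    age
        Scalar or array of ages in years (``>= 0``; ``> 0`` for forms with
        ``requires_positive_age``).

    Returns
    -------
    Expected size in cm, same shape as ``age``.  Out-of-regime parameters can
    produce non-positive or non-finite values; use
    :func:`check_curve_validity` to screen them.
    """
    form = get_form(form)
    p = _check_params(form, params)
    x = np.asarray(age, dtype=float)
    _check_domain(form, x)
    with np.errstate(all="ignore"):
        return form._fn(x, *p)


def curve_with_gradient(form: "str | ModelForm", params: Sequence[float], age):
    """Evaluate a curve and its gradient with respect to the parameters.

    Returns ``(f, grads)`` where ``grads`` is a tuple of ``n_params`` arrays,
    each broadcast to the shape of ``f``.  Used by the likelihood machinery;
    parameters may be arrays broadcast against ``age``.
    """
    form = get_form(form)
    x = np.asarray(age, dtype=float)
    _check_domain(form, x)
    p = params
    if np.ndim(p) == 1 and not isinstance(p, (list, tuple)):
        p = tuple(p)
    if len(p) != form.n_params:
        raise ValueError(f"{form.abbreviation} takes {form.n_params} parameters")
    with np.errstate(all="ignore"):
        f = form._fn(x, *p)
        grads = form._grad(x, *p)
    return f, grads


@dataclass(frozen=True)
class CurveValidity:
    ok: bool
    first_violation_age: float | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


def check_curve_validity(
    form: "str | ModelForm", params: Sequence[float], age_grid
) -> CurveValidity:
    """Check that f(x) is finite and strictly positive over an age grid.

    Trait-linear parameter predictors can yield parameter combinations whose
    curve dips to zero or below, which breaks the lognormal link; this screen
    reports the first violating age (the grid is scanned in the order given).
    """
    grid = np.atleast_1d(np.asarray(age_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("age_grid must be non-empty")
    f = evaluate_curve(form, params, grid)
    bad = ~np.isfinite(f) | (f <= 0.0)
    if np.any(bad):
        return CurveValidity(False, float(grid[np.argmax(bad)]))
    return CurveValidity(True, None)
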