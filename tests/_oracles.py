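"""Independent oracles used by the test suite.

The curve transcriptions here are written directly from the algebraic
definitions via sympy, deliberately sharing no code with the package, and
serve as the reference implementation the registry is checked against.
"""

import numpy as np
import sympy as sp

_x, _a, _b, _w = sp.symbols("x a b w", positive=False)

# literal transcriptions of the eleven curve equations
SYMBOLIC = {
    "EXP2": _a + _b * sp.log(_x),
    "KOBLOG2": _a * sp.log(1 + _x / _b),
    "MONOD2": _a * _x / (_b + _x),
    "NEGEXP2": _a * (1 - sp.exp(-_b * _x)),
    "PWR2": _a * _x**_b,
    "PWR3": _a * _x**_b - _w / _x,
    "ARCH3": _a / (_b + _w**_x),
    "HS3": _a / (1 + sp.exp(-_b * (_x - _w))),
    "HSlog3": _a / (1 + sp.exp(-_b * (sp.log(_x) - _w))),
    "LOG3": _a / (1 + sp.exp(-_b * _x + _w)),
    "WEIB3": _a * (1 - sp.exp(-_b * _x**_w)),
}

_TWO = ("EXP2", "KOBLOG2", "MONOD2", "NEGEXP2", "PWR2")


def oracle_fn(abbrev):
    """Vectorized numeric version of the literal transcription."""
    expr = SYMBOLIC[abbrev]
    args = (_x, _a, _b) if abbrev in _TWO else (_x, _a, _b, _w)
    return sp.lambdify(args, expr, modules="numpy")


def oracle_grad(abbrev):
    """Vectorized parameter gradient of the literal transcription."""
    expr = SYMBOLIC[abbrev]
    params = (_a, _b) if abbrev in _TWO else (_a, _b, _w)
    args = (_x, *params)
    return [sp.lambdify(args, sp.diff(expr, p), modules="numpy") for p in params]


def draw_positive_growth_params(abbrev, rng):
    """One parameter vector inside the documented positive-growth regime."""
    a = rng.uniform(5.0, 300.0)
    if abbrev == "EXP2":
        # keep f positive on x >= 0.1: a + b*log(0.1) > 0
        b = rng.uniform(0.1, a / 3.0)
        return np.array([a, b])
    if abbrev == "KOBLOG2":
        return np.array([a, rng.uniform(0.5, 30.0)])
    if abbrev == "MONOD2":
        return np.array([a, rng.uniform(0.5, 40.0)])
    if abbrev == "NEGEXP2":
        return np.array([a, rng.uniform(0.02, 1.0)])
    if abbrev == "PWR2":
        return np.array([a / 20.0, rng.uniform(0.2, 1.5)])
    if abbrev == "PWR3":
        return np.array([a / 20.0, rng.uniform(0.2, 1.5), rng.uniform(0.0, 0.05)])
    if abbrev == "ARCH3":
        return np.array([a, rng.uniform(0.5, 3.0), rng.uniform(0.05, 0.95)])
    if abbrev in ("HS3",):
        return np.array([a, rng.uniform(0.05, 1.0), rng.uniform(2.0, 40.0)])
    if abbrev == "HSlog3":
        return np.array([a, rng.uniform(0.3, 3.0), rng.uniform(0.0, 3.5)])
    if abbrev == "LOG3":
        b = rng.uniform(0.05, 1.0)
        return np.array([a, b, b * rng.uniform(2.0, 40.0)])
    if abbrev == "WEIB3":
        return np.array([a, rng.uniform(0.01, 0.5), rng.uniform(0.5, 2.0)])
    raise KeyError(abbrev)
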