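"""Lifespan trajectory models: fitting, AIC selection, landmarks.

Five candidate families describe a metric's course over age t (years):

* linear        y = a + b t                      (k = 2)
* quadratic     y = a + b t + c t^2              (k = 3)
* cubic         y = a + b t + c t^2 + d t^3      (k = 4)
* poisson       y = a + b t exp(-c t)            (k = 3)
* exponential   y = a + b exp(-c t), b, c > 0    (k = 3)

The "poisson" curve is a 3-parameter non-symmetric bump/dip used for
white-matter lifespan modelling; with b < 0 it has a single minimum at
t = 1/c, capturing a steep childhood decline followed by a gradual adult
recovery.  The decreasing exponential captures a steep early drop that
levels off.

All families are fitted by ordinary least squares.  Polynomials are solved
in closed form.  The two nonlinear families are fitted by variable
projection: the decay rate c is profiled over a deterministic log-spaced
grid (the linear part (a, b) is solved in closed form at each c), and the
best grid point is refined by bounded scalar minimization — no randomness,
so fits are bit-reproducible.

Model selection follows an AIC parsimony rule: all fits within two AIC
units of the best are regarded as similarly accurate, and among those the
one with the fewest parameters wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .core import AGE_RANGE

__all__ = [
    "FAMILY_ORDER",
    "FAMILY_K",
    "TrajectoryFit",
    "predict",
    "fit_family",
    "fit_all_families",
    "compute_aic",
    "select_model",
    "extract_landmarks",
    "poisson_from_min_and_point",
    "exponential_from_anchors",
    "quadratic_from_vertex_and_endpoints",
    "cubic_through_points",
]

#: Fixed family precedence for exact ties (fitting order and tie-break).
FAMILY_ORDER = ("linear", "quadratic", "cubic", "poisson", "exponential")

FAMILY_K = {"linear": 2, "quadratic": 3, "cubic": 4,
            "poisson": 3, "exponential": 3}

#: Variable-projection grid for the decay rate c (1/years): 200 log-spaced
#: points covering time constants from 0.5 to 200 years.
_C_GRID = np.logspace(np.log10(1.0 / 200.0), np.log10(2.0), 200)

#: Relative RSS floor: a fit whose RSS is below this times n * max|y|^2 is
#: numerically exact (its RSS is rounding residue) and gets the AIC = -inf
#: sentinel, so selection among exact fits reduces to fewest parameters.
_EXACT_REL = 1e-20


def predict(family: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate a family at ages ``t``."""
    p = np.asarray(params, dtype=float)
    t = np.asarray(t, dtype=float)
    if family == "linear":
        return p[0] + p[1] * t
    if family == "quadratic":
        return p[0] + p[1] * t + p[2] * t ** 2
    if family == "cubic":
        return p[0] + p[1] * t + p[2] * t ** 2 + p[3] * t ** 3
    if family == "poisson":
        return p[0] + p[1] * t * np.exp(-p[2] * t)
    if family == "exponential":
        return p[0] + p[1] * np.exp(-p[2] * t)
    raise ValueError(f"unknown trajectory family: {family!r}")


@dataclass
class TrajectoryFit:
    """One fitted family: parameters, fit quality, and derived landmarks."""

    family: str
    params: np.ndarray
    k: int
    rss: float
    n: int
    aic: float = field(init=False)
    converged: bool = True
    selected: bool = False

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.aic = compute_aic(self.rss, self.n, self.k)

    def __call__(self, t):
        return predict(self.family, self.params, t)

    @property
    def exact(self) -> bool:
        return self.rss == 0.0

    def landmarks(self, age_range: tuple = AGE_RANGE) -> dict:
        return extract_landmarks(self, age_range)


def compute_aic(rss: float, n: int, k: int) -> float:
    """AIC = n ln(RSS/n) + 2 (k + 1), the Gaussian-likelihood form with the
    error variance counted as a parameter and constants dropped (valid for
    comparisons within one dataset).  An exact fit returns -inf."""
    if n <= k:
        raise ValueError("AIC requires n > k")
    if rss <= 0.0:
        return float("-inf")
    return n * np.log(rss / n) + 2.0 * (k + 1)


def _poly_fit(t: np.ndarray, y: np.ndarray, degree: int):
    x = np.vander(t, degree + 1, increasing=True)
    params, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(np.square(y - x @ params).sum())
    return params, rss


def _varpro_rss(t: np.ndarray, y: np.ndarray, basis_fn, c: float):
    """Profiled RSS at decay rate c with closed-form linear part (a, b)."""
    phi = basis_fn(t, c)
    x = np.column_stack([np.ones_like(t), phi])
    params, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(np.square(y - x @ params).sum())
    return rss, params


def _varpro_fit(t: np.ndarray, y: np.ndarray, basis_fn,
                require_b_positive: bool = False):
    rss_grid = np.empty_like(_C_GRID)
    ab_grid = np.empty((_C_GRID.size, 2))
    for i, c in enumerate(_C_GRID):
        rss_grid[i], ab_grid[i] = _varpro_rss(t, y, basis_fn, c)

    order = np.argsort(rss_grid, kind="stable")
    best = order[0]
    if require_b_positive:
        valid = np.flatnonzero(ab_grid[order, 1] >= 0)
        if valid.size:
            best = order[valid[0]]

    lo = _C_GRID[max(best - 1, 0)]
    hi = _C_GRID[min(best + 1, _C_GRID.size - 1)]
    converged = True
    if hi > lo:
        res = minimize_scalar(
            lambda c: _varpro_rss(t, y, basis_fn, c)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        converged = bool(res.success)
        c_best = float(res.x) if res.success else float(_C_GRID[best])
    else:
        c_best = float(_C_GRID[best])

    rss, ab = _varpro_rss(t, y, basis_fn, c_best)
    if rss > rss_grid[best]:                     # refinement never worsens
        c_best = float(_C_GRID[best])
        rss, ab = rss_grid[best], ab_grid[best]
    if require_b_positive and ab[1] < 0:
        # fall back to the flat fit b = 0 (family degenerates to a constant)
        a = float(np.mean(y))
        return np.array([a, 0.0, c_best]), float(
            np.square(y - a).sum()), False
    return np.array([ab[0], ab[1], c_best]), rss, converged


def fit_family(ages: np.ndarray, values: np.ndarray,
               family: str) -> TrajectoryFit:
    """Fit one family to (age, value) pairs by ordinary least squares."""
    t = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("ages and values must be matching 1-D arrays")
    k = FAMILY_K.get(family)
    if k is None:
        raise ValueError(f"unknown trajectory family: {family!r}")
    if t.size < k + 2:
        raise ValueError(f"need at least {k + 2} points to fit {family}")
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all ages identical")

    converged = True
    if family == "linear":
        params, rss = _poly_fit(t, y, 1)
    elif family == "quadratic":
        params, rss = _poly_fit(t, y, 2)
    elif family == "cubic":
        params, rss = _poly_fit(t, y, 3)
    elif family == "poisson":
        params, rss, converged = _varpro_fit(
            t, y, lambda tt, c: tt * np.exp(-c * tt))
    else:  # exponential, decreasing: b >= 0, c > 0
        params, rss, converged = _varpro_fit(
            t, y, lambda tt, c: np.exp(-c * tt), require_b_positive=True)

    scale = max(float(np.max(np.abs(y))) ** 2, 1e-300)
    if rss <= _EXACT_REL * t.size * scale:
        rss = 0.0
    return TrajectoryFit(family=family, params=params, k=k, rss=rss,
                         n=t.size, converged=converged)


def fit_all_families(ages: np.ndarray, values: np.ndarray,
                     families: tuple = FAMILY_ORDER) -> list[TrajectoryFit]:
    """Fit every candidate family and mark the AIC-selected one."""
    fits = [fit_family(ages, values, f) for f in families]
    winner = select_model(fits)
    for f in fits:
        f.selected = f is winner
    return fits


def select_model(fits: list[TrajectoryFit]) -> TrajectoryFit:
    """AIC parsimony rule.

    Candidates are all fits with AIC within two units of the minimum; among
    them the fewest-parameter fit wins; ties on parameter count go to the
    lower AIC; exact ties fall back to the fixed family precedence order.
    """
    if not fits:
        raise ValueError("select_model needs at least one fit")
    aics = np.array([f.aic for f in fits])
    best = np.min(aics)
    if np.isneginf(best):
        candidates = [f for f in fits if np.isneginf(f.aic)]
    else:
        candidates = [f for f in fits if f.aic <= best + 2.0]
    candidates.sort(key=lambda f: (f.k, f.aic, FAMILY_ORDER.index(f.family)))
    return candidates[0]


def extract_landmarks(fit: TrajectoryFit,
                      age_range: tuple = AGE_RANGE) -> dict:
    """Extrema and endpoint values of a fitted trajectory.

    Returns a dict with ``value_at_start``/``value_at_end`` (the fitted
    values at the age-range endpoints) and, when the family has stationary
    points inside the range, a list of ``extrema`` entries
    (age, value, kind in {minimum, maximum}).  Monotone families (linear,
    exponential, and degenerate cases) report endpoints only.
    """
    lo, hi = age_range
    p = fit.params
    stationary: list[float] = []
    if fit.family == "quadratic" and p[2] != 0:
        stationary = [-p[1] / (2.0 * p[2])]
    elif fit.family == "cubic":
        # roots of the derivative 3d t^2 + 2c t + b
        der = np.array([3.0 * p[3], 2.0 * p[2], p[1]])
        if der[0] != 0:
            roots = np.roots(der)
        elif der[1] != 0:
            roots = np.roots(der[1:])
        else:
            roots = np.array([])
        stationary = [float(r.real) for r in np.atleast_1d(roots)
                      if abs(np.imag(r)) < 1e-9]
    elif fit.family == "poisson" and p[1] != 0 and p[2] > 0:
        stationary = [1.0 / p[2]]

    extrema = []
    eps = 1e-4
    for t0 in sorted(stationary):
        if not lo <= t0 <= hi:
            continue
        before = fit(max(t0 - eps, lo))
        after = fit(min(t0 + eps, hi))
        v = float(fit(t0))
        if v <= before and v <= after:
            kind = "minimum"
        elif v >= before and v >= after:
            kind = "maximum"
        else:
            continue                              # inflection, not extremum
        extrema.append({"age": float(t0), "value": v, "kind": kind})

    return {
        "value_at_start": float(fit(lo)),
        "value_at_end": float(fit(hi)),
        "extrema": extrema,
    }


# ---------------------------------------------------------------------------
# Anchor constructors: build exact family parameters from landmark values.
# These turn printed lifespan landmarks (e.g. "minimum 0.12 at age 30") into
# generating curves for the synthetic cohorts.

def poisson_from_min_and_point(t_min: float, y_min: float,
                               t0: float, y0: float) -> np.ndarray:
    """Poisson-curve parameters with the minimum at (t_min, y_min) and the
    curve passing through (t0, y0).  The extremum of b t exp(-c t) is at
    t = 1/c, so c = 1/t_min; a and b then solve a 2x2 linear system."""
    if t_min <= 0 or t0 <= 0 or t0 == t_min:
        raise ValueError("anchor ages must be positive and distinct")
    c = 1.0 / t_min
    f = lambda t: t * np.exp(-c * t)
    mat = np.array([[1.0, f(t_min)], [1.0, f(t0)]])
    a, b = np.linalg.solve(mat, np.array([y_min, y0]))
    return np.array([a, b, c])


def exponential_from_anchors(t1: float, y1: float, t2: float, y2: float,
                             t3: float, y3: float) -> np.ndarray:
    """Decreasing-exponential parameters through three anchors
    (t1 < t2 < t3, y1 > y2 > y3).  The decay rate solves
    (e^{-c t1} - e^{-c t2}) / (e^{-c t2} - e^{-c t3}) = (y1-y2)/(y2-y3)
    by bisection; a and b follow in closed form."""
    if not (t1 < t2 < t3 and y1 > y2 > y3):
        raise ValueError("anchors must be strictly decreasing over age")
    target = (y1 - y2) / (y2 - y3)

    def ratio(c):
        e1, e2, e3 = np.exp(-c * t1), np.exp(-c * t2), np.exp(-c * t3)
        return (e1 - e2) / (e2 - e3) - target

    from scipy.optimize import brentq
    c = brentq(ratio, 1e-6, 2.0, xtol=1e-14)
    b = (y1 - y2) / (np.exp(-c * t1) - np.exp(-c * t2))
    a = y1 - b * np.exp(-c * t1)
    return np.array([a, b, c])


def quadratic_from_vertex_and_endpoints(t_vertex: float,
                                        t1: float, y1: float,
                                        t2: float, y2: float) -> np.ndarray:
    """Quadratic with its vertex at age ``t_vertex`` passing through the two
    endpoint anchors.  The vertex condition b = -2 c t_vertex makes the
    remaining system linear in (a, c)."""
    m1 = t1 ** 2 - 2.0 * t_vertex * t1
    m2 = t2 ** 2 - 2.0 * t_vertex * t2
    mat = np.array([[1.0, m1], [1.0, m2]])
    a, c = np.linalg.solve(mat, np.array([y1, y2]))
    b = -2.0 * c * t_vertex
    return np.array([a, b, c])


def cubic_through_points(anchors: list[tuple[float, float]]) -> np.ndarray:
    """Interpolating cubic through exactly four (age, value) anchors."""
    if len(anchors) != 4:
        raise ValueError("a cubic is determined by exactly four anchors")
    t = np.array([p[0] for p in anchors], dtype=float)
    y = np.array([p[1] for p in anchors], dtype=float)
    return np.linalg.solve(np.vander(t, 4, increasing=True), y)
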