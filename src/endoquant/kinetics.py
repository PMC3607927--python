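"""Sigmoidal internalization kinetics: curve fitting, k_max and half-time.

The time course of the internalization ratio (fraction of quantum-dot-labeled
ligand inside the cell) is sigmoidal in time.  Two standard four-parameter
families are supported:

``logistic`` (default)
    The symmetric logistic in time,

        y(t) = a1 + (a2 - a1) / (1 + exp(-(t - x0) / dx))

    with baseline ``a1``, plateau ``a2``, center ``x0`` (min) and time
    constant ``dx`` (min).  Its slope is maximal at t = x0 with the closed
    form k_max = (a2 - a1) / (4 dx).

``log_logistic``
    The power-law (log-logistic / Hill-type) form,

        y(t) = a2 + (a1 - a2) / (1 + (t / x0)^p),   y(0) = a1,

    with dimensionless power ``p``.  This is the truth model of the
    synthetic-data generator and is exactly anchored at the t = 0 ratio.

Both families are fit by bounded least squares with a small multi-start
grid; baseline and plateau are constrained to physical fractions [0, 1]
by default.  The maximal internalization rate ``k_max`` (min^-1) is the
maximum of dy/dt located on a dense time grid with local refinement, and
the characteristic half-time is ln(2)/k_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "LogisticFit",
    "logistic_value",
    "logistic_derivative",
    "fit_logistic",
    "k_max",
    "half_time",
    "analytic_k_max",
]

_P_LO, _P_HI = 0.2, 20.0  # power bounds; p >= 0.2 avoids the infinite-slope corner


@dataclass
class LogisticFit:
    """Fitted sigmoid parameters plus derived rate constants.

    ``p`` is the power of the log-logistic family; ``dx`` the time constant
    of the symmetric logistic.  Exactly one of them is set, according to
    ``family``.  ``k_max`` (min^-1), ``t_at_kmax`` and ``t_half`` (min) are
    filled in by :func:`fit_logistic`.
    """

    a1: float
    a2: float
    x0: float
    p: float | None = None
    dx: float | None = None
    family: str = "logistic"
    k_max: float | None = None
    t_at_kmax: float | None = None
    t_half: float | None = None
    r_squared: float | None = None
    converged: bool = True
    half_time_definition: str = "ln2_over_kmax"
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in ("logistic", "log_logistic"):
            raise ValueError(f"unknown family: {self.family!r}")
        if self.family == "logistic" and self.dx is None:
            raise ValueError("logistic family requires dx")
        if self.family == "log_logistic" and self.p is None:
            raise ValueError("log_logistic family requires p")


def logistic_value(fit: LogisticFit, t):
    """Evaluate the fitted sigmoid at time(s) ``t`` (minutes, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    a1, a2 = fit.a1, fit.a2
    if fit.family == "logistic":
        z = np.clip(-(t - fit.x0) / fit.dx, -700, 700)
        y = a1 + (a2 - a1) / (1.0 + np.exp(z))
    else:
        with np.errstate(divide="ignore"):
            u = np.where(t > 0, t / fit.x0, 0.0)
            y = a2 + (a1 - a2) / (1.0 + u**fit.p)
        y = np.where(t == 0, a1, y)  # y(0) = a1 by the t -> 0 limit
    return float(y) if y.ndim == 0 else y


def logistic_derivative(fit: LogisticFit, t):
    """dy/dt of the fitted sigmoid.

    Symmetric logistic:  dy/dt = (a2-a1) e / (dx (1+e)^2), e = exp((t-x0)/dx).
    Log-logistic:        dy/dt = (a2-a1) p (t/x0)^p / (t (1+(t/x0)^p)^2),
    with the t -> 0 limit handled analytically (0 for p > 1, (a2-a1)/x0 for
    p = 1, divergent for p < 1).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    a1, a2 = fit.a1, fit.a2
    if fit.family == "logistic":
        # s(1-s)/dx form avoids exp overflow far from the center
        z = np.clip((t - fit.x0) / fit.dx, -700, 700)
        s = 1.0 / (1.0 + np.exp(-z))
        d = (a2 - a1) * s * (1.0 - s) / fit.dx
        return float(d) if d.ndim == 0 else d
    p, x0 = fit.p, fit.x0
    out = np.empty(np.shape(t), dtype=float)
    tt = np.atleast_1d(t)
    res = np.atleast_1d(out)
    pos = tt > 0
    s = (tt[pos] / x0) ** p
    res[pos] = (a2 - a1) * p * s / (tt[pos] * (1.0 + s) ** 2)
    if np.any(~pos):
        res[~pos] = 0.0 if p > 1 else ((a2 - a1) / x0 if p == 1 else math.inf)
    return float(out) if out.ndim == 0 else out


def analytic_k_max(fit: LogisticFit) -> tuple[float, float]:
    """Closed-form maximum of dy/dt, as an independent check of :func:`k_max`.

    Symmetric logistic: max at t = x0, value (a2-a1)/(4 dx).  Log-logistic
    (p > 1): setting the second derivative to zero with s = (t/x0)^p gives
    s* = (p-1)/(p+1), hence t* = x0 ((p-1)/(p+1))^(1/p).
    """
    if fit.family == "logistic":
        return (fit.a2 - fit.a1) / (4.0 * fit.dx), fit.x0
    if fit.p <= 1:
        raise ValueError("closed form requires p > 1 for the log-logistic")
    s_star = (fit.p - 1.0) / (fit.p + 1.0)
    t_star = fit.x0 * s_star ** (1.0 / fit.p)
    return float(logistic_derivative(fit, t_star)), float(t_star)


def k_max(
    fit: LogisticFit,
    t_max: float,
    n_grid: int = 10_000,
    t_min: float = 0.01,
) -> tuple[float, float]:
    """Maximal slope of the fitted curve over a dense grid, locally refined.

    Returns ``(k_max, t_at_kmax)`` in (min^-1, min).  The grid spans
    [t_min, t_max]; t = 0 is excluded so log-logistic fits with p <= 1
    (divergent slope at the origin) report the maximum over observable
    times rather than an infinity.  Deterministic given fit and grid.
    """
    if not fit.converged:
        raise ValueError("cannot derive k_max from a non-converged fit")
    if t_max <= t_min:
        raise ValueError("t_max must exceed t_min")
    grid = np.linspace(t_min, t_max, n_grid)
    dy = logistic_derivative(fit, grid)
    i = int(np.argmax(dy))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda t: -logistic_derivative(fit, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_star = float(res.x)
    k = float(logistic_derivative(fit, t_star))
    if dy[i] > k:  # refinement may only improve on the grid point
        t_star, k = float(grid[i]), float(dy[i])
    return k, t_star


def half_time(fit: LogisticFit, definition: str = "ln2_over_kmax") -> float:
    """Characteristic internalization half-time in minutes.

    The default ``ln2_over_kmax`` treats the maximal slope as an effective
    first-order rate constant; ``midpoint_x0`` returns the curve center.
    """
    if definition == "ln2_over_kmax":
        if fit.k_max is None or fit.k_max <= 0:
            raise ValueError("half-time undefined: k_max is zero or missing")
        return math.log(2.0) / fit.k_max
    if definition == "midpoint_x0":
        return fit.x0
    raise ValueError(f"unknown half-time definition: {definition!r}")


def _model(theta, t, family):
    a1, a2, x0, s = theta
    t = np.asarray(t, dtype=float)
    if family == "logistic":
        return a1 + (a2 - a1) / (1.0 + np.exp(np.clip(-(t - x0) / s, -700, 700)))
    with np.errstate(divide="ignore"):
        u = np.where(t > 0, t / x0, 0.0)
        y = a2 + (a1 - a2) / (1.0 + u**s)
    return np.where(t == 0, a1, y)


def fit_logistic(
    times,
    values,
    weights=None,
    init=None,
    family: str = "logistic",
    a_bounds: tuple[float, float] = (0.0, 1.0),
    half_time_definition: str = "ln2_over_kmax",
    kmax_grid: int = 10_000,
) -> LogisticFit:
    """Bounded least-squares fit of a four-parameter sigmoid to a time course.

    Parameters
    ----------
    times, values
        Sampling times (minutes, >= 0) and internalization fractions; at
        least 4 points (4 free parameters).
    weights
        Optional per-point weights (e.g. n or 1/sem^2); residuals are
        multiplied by sqrt(weight).  Unweighted by default.
    init
        Optional explicit start ``(a1, a2, x0, shape)`` where shape is dx
        (logistic) or p (log_logistic).  Otherwise a multi-start grid is
        used: a1 = min(y), a2 = max(y), x0 in {time of the value closest to
        the midpoint, median time}, and dx in {range/10, range/4, range/2}
        or p in {1, 2, 4}.  Smallest residual wins; ties break toward the
        smallest shape parameter.
    family
        ``"logistic"`` (symmetric, default) or ``"log_logistic"``.
    a_bounds
        Bounds applied to both a1 and a2.  Ratios are physical fractions,
        hence the [0, 1] default.

    Returns a :class:`LogisticFit` carrying k_max, t_at_kmax, the half-time
    under the requested definition, and R^2.
    """
    if family not in ("logistic", "log_logistic"):
        raise ValueError(f"unknown family: {family!r}")
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points to fit 4 parameters")
    if np.any(t < 0) or not np.all(np.isfinite(y)):
        raise ValueError("times must be >= 0 and values finite")
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if w.shape != y.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per point")
    else:
        w = np.ones_like(y)

    t_span = float(np.max(t))
    if t_span <= 0:
        raise ValueError("at least one time must be positive")
    a_lo, a_hi = a_bounds
    if family == "logistic":
        # center may sit left of t=0 for curves already rising at time zero;
        # dx >= span/100 keeps the transition resolvable on the sampled grid
        lb = np.array([a_lo, a_lo, -t_span, t_span / 100.0])
        ub = np.array([a_hi, a_hi, 10.0 * t_span, 10.0 * t_span])
        shape_starts = [t_span / 10.0, t_span / 4.0, t_span / 2.0]
    else:
        lb = np.array([a_lo, a_lo, 1e-6, _P_LO])
        ub = np.array([a_hi, a_hi, 10.0 * t_span, _P_HI])
        shape_starts = [1.0, 2.0, 4.0]

    def residuals(theta):
        return w * (_model(theta, t, family) - y)

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    else:
        y_lo, y_hi = float(np.min(y)), float(np.max(y))
        mid = 0.5 * (y_lo + y_hi)
        t_mid = float(t[np.argmin(np.abs(y - mid))])
        x0_starts = sorted({max(t_mid, 1e-3), max(float(np.median(t)), 1e-3)})
        starts = [
            np.array([y_lo, y_hi, x0s, s0]) for s0 in shape_starts for x0s in x0_starts
        ]

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lb, ub)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15 or (
            abs(sol.cost - best.cost) <= 1e-15 and sol.x[3] < best.x[3]
        ):
            best = sol

    if best is None or not best.success:
        return LogisticFit(
            math.nan, math.nan, math.nan, p=math.nan, dx=math.nan,
            family=family, converged=False,
        )

    a1, a2, x0, shape = (float(v) for v in best.x)
    fit = LogisticFit(
        a1, a2, x0,
        p=shape if family == "log_logistic" else None,
        dx=shape if family == "logistic" else None,
        family=family,
        half_time_definition=half_time_definition,
    )
    ss_res = float(np.sum((_model(best.x, t, family) - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    fit.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit.notes["n_points"] = int(t.size)
    fit.notes["weighted"] = weights is not None

    if a2 - a1 < 1e-9:
        fit.k_max, fit.t_at_kmax = 0.0, math.nan
        fit.notes["degenerate"] = "a1 ~ a2 (flat time course)"
        return fit

    fit.k_max, fit.t_at_kmax = k_max(fit, t_max=1.1 * t_span, n_grid=kmax_grid)
    if fit.k_max > 0:
        fit.t_half = half_time(fit, half_time_definition)
    return fit
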