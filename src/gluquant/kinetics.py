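"""Exponential turnover kinetics and linear regression.

Cleavage / turnover time courses (normalized band intensity vs. time)
are fitted with a single exponential with plateau,

    value(t) = C + (A - C) * exp(-t / tau),

where ``A`` is the initial level, ``C`` the plateau (the long-lived
fraction), and ``tau`` the time constant in the units of the input time
axis.  The half-life is ``tau * ln 2``; reported half-lives round to
the integer minute when the time unit is minutes.  A plateau-free
variant (C fixed at 0) is available for curves known to decay fully.

``linear_fit`` is ordinary least squares with the two-sided t test of
zero slope, as used to relate the synchronous release fraction to the
spontaneous release rate across conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ExpFitResult",
    "RegressionResult",
    "fit_single_exponential",
    "half_life",
    "reported_half_life",
    "linear_fit",
]

LN2 = math.log(2.0)


@dataclass
class ExpFitResult:
    amplitude: float
    plateau: float
    tau: float
    r_squared: float
    residuals: np.ndarray
    param_se: dict[str, float]
    fixed_plateau: bool

    @property
    def t_half(self) -> float:
        """Half-life, exactly tau * ln 2."""
        return self.tau * LN2

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.plateau + (self.amplitude - self.plateau) * np.exp(-t / self.tau)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def half_life(tau: float) -> float:
    """t_1/2 = tau * ln 2 (same units as tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return tau * LN2


def reported_half_life(tau: float, units: str = "min") -> float:
    """Half-life as it would be quoted: integer minutes, otherwise raw."""
    t = half_life(tau)
    return float(round(t)) if units == "min" else t


def _model(t, amplitude, plateau, tau):
    return plateau + (amplitude - plateau) * np.exp(-t / tau)


def fit_single_exponential(curve: pd.DataFrame, fix_plateau_to_zero: bool = False,
                           allow_increasing: bool = False) -> ExpFitResult:
    """Least-squares fit of a single exponential with plateau.

    ``curve`` needs ``time`` and ``value`` columns.  Initialization: A
    from the first value, C from the minimum, tau from a log-linear fit
    of (value - C).  tau is constrained positive; convergence tolerance
    is 1e-8 on the parameters.  A clearly increasing series is refused
    (decay model) unless ``allow_increasing`` is set.
    """
    t = np.asarray(curve["time"], dtype=float)
    y = np.asarray(curve["value"], dtype=float)
    min_points = 3 if fix_plateau_to_zero else 4
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points for this fit")
    if np.ptp(y) == 0:
        raise ValueError("flat series: exponential parameters are not identifiable")
    if y[-1] > y[0] and not allow_increasing:
        warnings.warn("series increases over time; a decay model does not apply")
        raise ValueError(
            "refusing to fit a decay model to an increasing series; "
            "pass allow_increasing=True to force"
        )

    a0 = float(y[0])
    c0 = 0.0 if fix_plateau_to_zero else float(y.min())
    resid = y - c0
    pos = resid > 0
    if pos.sum() >= 2:
        slope, _ = np.polyfit(t[pos], np.log(resid[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else float(t[-1] - t[0]) or 1.0
    else:
        tau0 = float(t[-1] - t[0]) or 1.0
    tau0 = max(tau0, 1e-6)

    tiny = 1e-12
    try:
        if fix_plateau_to_zero:
            popt, pcov = optimize.curve_fit(
                lambda tt, a, tau: _model(tt, a, 0.0, tau), t, y,
                p0=[a0, tau0], bounds=([-np.inf, tiny], [np.inf, np.inf]),
                xtol=1e-8, ftol=1e-8, maxfev=20_000,
            )
            amplitude, tau = popt
            plateau = 0.0
            se = np.sqrt(np.diag(pcov))
            param_se = {"amplitude": float(se[0]), "plateau": 0.0, "tau": float(se[1])}
        else:
            popt, pcov = optimize.curve_fit(
                _model, t, y, p0=[a0, c0, tau0],
                bounds=([-np.inf, -np.inf, tiny], [np.inf, np.inf, np.inf]),
                xtol=1e-8, ftol=1e-8, maxfev=20_000,
            )
            amplitude, plateau, tau = popt
            se = np.sqrt(np.diag(pcov))
            param_se = {"amplitude": float(se[0]), "plateau": float(se[1]),
                        "tau": float(se[2])}
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential fit did not converge: {err}; "
            f"initial guess was A={a0:.4g}, C={c0:.4g}, tau={tau0:.4g}"
        ) from err

    residuals = y - _model(t, amplitude, plateau, tau)
    ss_res = float((residuals ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    if t[-1] - t[0] < tau:
        warnings.warn(
            "time span is shorter than the fitted tau; the estimate may be unreliable"
        )
    return ExpFitResult(
        amplitude=float(amplitude), plateau=float(plateau), tau=float(tau),
        r_squared=r_squared, residuals=residuals, param_se=param_se,
        fixed_plateau=fix_plateau_to_zero,
    )


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares with two-sided p value for zero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
    )
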