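"""Logistic growth-curve fitting and doubling times from OD600 series.

The model is the three-parameter logistic

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r t))

with carrying capacity K (OD units), inoculum N0 and intrinsic growth rate
r (per minute for times in minutes). The doubling time is ln(2)/r -- the
doubling time of the early, unsaturated phase. There is no lag-phase term;
curves with a pronounced lag will absorb it into N0 and r (documented
limitation of this model family).

Fitting is bounded least squares (K, N0, r > 0) with the standard
initialization: K from the plateau, N0 from the first reading, r from the
steepest 5-point slope of log OD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io import ODSeries

__all__ = ["LogisticFit", "logistic", "fit_logistic", "doubling_time"]

LN2 = math.log(2.0)


@dataclass
class LogisticFit:
    """Fitted logistic parameters; fields are None when not converged."""

    strain_id: str
    converged: bool
    K: float | None = None
    N0: float | None = None
    r: float | None = None
    doubling_time: float | None = None
    rss: float | None = None
    message: str = ""


def logistic(t, K, N0, r):
    """Logistic population size at time t."""
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * np.asarray(t, float)))


def doubling_time(r: float) -> float:
    """ln(2)/r, in the time units of r."""
    if r <= 0:
        raise ValueError("growth rate must be positive")
    return LN2 / r


def fit_logistic(
    series: ODSeries,
    blank: float = 0.0,
    ftol: float = 1e-8,
    max_nfev: int = 500,
) -> LogisticFit:
    """Fit the logistic model to one OD600 series.

    ``blank`` is an optional media-blank OD subtracted before fitting.
    A series with no detectable growth (final plateau within 5% of the
    starting density, or a non-positive fitted rate) is reported as not
    converged rather than given a meaningless doubling time.
    """
    t = series.times
    od = series.od - blank
    if np.any(od <= 0):
        return LogisticFit(series.strain_id, False,
                           message="non-positive OD after blank subtraction")
    if np.max(od) <= 1.05 * od[0]:
        return LogisticFit(series.strain_id, False,
                           message="no growth: plateau within 5% of start")

    p0 = (float(np.max(od)), float(od[0]), _initial_rate(t, od))
    try:
        popt, _ = curve_fit(
            logistic, t, od, p0=p0,
            bounds=([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
            ftol=ftol, xtol=1e-12, max_nfev=max_nfev,
        )
    except (RuntimeError, ValueError) as exc:
        return LogisticFit(series.strain_id, False, message=str(exc))
    K, N0, r = (float(v) for v in popt)
    if not (K > N0 > 0) or r <= 0:
        return LogisticFit(series.strain_id, False,
                           message="degenerate parameter estimate")
    rss = float(np.sum((logistic(t, K, N0, r) - od) ** 2))
    return LogisticFit(series.strain_id, True, K=K, N0=N0, r=r,
                       doubling_time=doubling_time(r), rss=rss)


def _initial_rate(t: np.ndarray, od: np.ndarray) -> float:
    """Slope of log OD over the steepest 5-point window (fallback 0.005/min)."""
    logs = np.log(od)
    n = len(t)
    best = 0.0
    for i in range(n - 4):
        dt = t[i + 4] - t[i]
        slope = (logs[i + 4] - logs[i]) / dt
        best = max(best, slope)
    return best if best > 0 else 0.005
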