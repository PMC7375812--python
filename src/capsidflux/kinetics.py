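"""Mono-exponential kinetic fitting and initial-flux estimation.

Nuclear accumulation traces are fitted with I(t) = A + I_max*(1 - e^(-tau*t)).
The quantity of interest is the initial flux J = I_max * tau, the slope of
the accumulation curve at t = 0, which is insensitive to late-time effects
(receptor recycling, back-leakage, pore crowding) that the mono-exponential
does not attempt to model.  A bi-exponential alternative is provided for
model comparison via AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trace import ExpKineticParams, IntensityTrace

__all__ = [
    "ExpFit",
    "BiExpFit",
    "correct_trace",
    "fit_monoexponential",
    "fit_biexponential",
    "initial_flux",
    "average_replicates",
]


@dataclass
class ExpFit:
    """Result of a mono-exponential fit."""

    params: ExpKineticParams
    se: Dict[str, float]
    r_squared: float
    converged: bool
    message: str = ""
    aic: float = math.nan

    @property
    def j(self) -> float:
        """Initial flux J = I_max * tau."""
        return self.params.i_max * self.params.tau


@dataclass
class BiExpFit:
    """Result of a bi-exponential fit I(t)=A + B1(1-e^-r1 t) + B2(1-e^-r2 t).

    Rates are ordered r1 >= r2.  ``delta_aic`` is AIC(bi) - AIC(mono): a
    positive value means the mono-exponential is preferred.
    """

    a: float
    b1: float
    rate1: float
    b2: float
    rate2: float
    r_squared: float
    converged: bool
    aic: float = math.nan
    delta_aic: float = math.nan

    def __post_init__(self) -> None:
        if self.rate1 < self.rate2:
            self.b1, self.b2 = self.b2, self.b1
            self.rate1, self.rate2 = self.rate2, self.rate1


def _as_arrays(trace: Union[IntensityTrace, Sequence[float]],
               times: Optional[Sequence[float]] = None):
    if isinstance(trace, IntensityTrace):
        return trace.times, trace.values
    if times is None:
        raise ValueError("times required when trace is a plain sequence")
    return np.asarray(times, float), np.asarray(trace, float)


def correct_trace(raw: IntensityTrace,
                  background: Union[float, np.ndarray, IntensityTrace],
                  n_dyes: int) -> IntensityTrace:
    """Background-subtract and brightness-rescale a raw trace.

    Output = (raw - background) / n_dyes, making intensities proportional to
    capsid concentration regardless of labelling ratio.  The fitted offset A
    is *not* subtracted here (that is a display-only convention).
    """
    if n_dyes < 1:
        raise ValueError("n_dyes must be >= 1")
    bg = background.values if isinstance(background, IntensityTrace) else background
    bg = np.asarray(bg, dtype=float)
    vals = (raw.values - bg) / n_dyes
    sd = raw.sd / n_dyes if raw.sd is not None else None
    return IntensityTrace(times=raw.times, values=vals, sd=sd,
                          n_fov=raw.n_fov, compartment=raw.compartment,
                          seed=raw.seed)


def _mono(t, a, i_max, tau):
    return a + i_max * (-np.expm1(-tau * t))


def _aic(resid: np.ndarray, k: int) -> float:
    n = resid.size
    rss = float(np.sum(resid ** 2))
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k


def fit_monoexponential(trace: Union[IntensityTrace, Sequence[float]],
                        times: Optional[Sequence[float]] = None,
                        init: Optional[ExpKineticParams] = None,
                        weights: Optional[np.ndarray] = None) -> ExpFit:
    """Nonlinear least-squares fit of the mono-exponential model.

    Initialisation (unless given): A <- first point, I_max <- last - first,
    tau <- 3 / time span; bounds tau >= 0, I_max >= 0, A free.  Weighted
    fitting (1/sd) is used only when ``weights`` is supplied.
    """
    t, y = _as_arrays(trace, times)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    span = float(t[-1] - t[0]) or 1.0
    if init is None:
        p0 = [float(y[0]), max(float(y[-1] - y[0]), 1e-9), 3.0 / span]
    else:
        p0 = [init.a, max(init.i_max, 1e-9), max(init.tau, 1e-9)]
    sigma = None if weights is None else 1.0 / np.asarray(weights, float)
    decreasing = y[-1] < y[0]
    try:
        popt, pcov = curve_fit(
            _mono, t, y, p0=p0, sigma=sigma,
            bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
        message = ""
    except RuntimeError as exc:
        popt = np.asarray(p0, float)
        pcov = np.full((3, 3), np.nan)
        converged = False
        message = f"curve_fit failed: {exc}"
    if decreasing and converged:
        message = "trace decreases: I_max/tau pinned near bound"
    resid = y - _mono(t, *popt)
    tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tot if tot > 0 else 1.0
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    params = ExpKineticParams(a=float(popt[0]), i_max=float(popt[1]),
                              tau=float(popt[2]))
    return ExpFit(params=params,
                  se={"a": float(perr[0]), "i_max": float(perr[1]),
                      "tau": float(perr[2])},
                  r_squared=r2, converged=converged, message=message,
                  aic=_aic(resid, 3))


def _bi(t, a, b1, r1, b2, r2):
    return a + b1 * (-np.expm1(-r1 * t)) + b2 * (-np.expm1(-r2 * t))


def fit_biexponential(trace: Union[IntensityTrace, Sequence[float]],
                      times: Optional[Sequence[float]] = None) -> BiExpFit:
    """Two-component fit, reported with its AIC difference vs the mono fit."""
    t, y = _as_arrays(trace, times)
    if t.size < 6:
        raise ValueError("need at least 6 time points")
    mono = fit_monoexponential(y, t)
    span = float(t[-1] - t[0]) or 1.0
    amp = max(float(y[-1] - y[0]), 1e-9)
    p0 = [float(y[0]), 0.7 * amp, 6.0 / span, 0.3 * amp, 0.6 / span]
    try:
        popt, _ = curve_fit(
            _bi, t, y, p0=p0,
            bounds=([-np.inf, 0, 0, 0, 0], [np.inf] + [np.inf] * 4),
            maxfev=40000)
        converged = True
    except RuntimeError:
        popt = np.asarray(p0, float)
        converged = False
    resid = y - _bi(t, *popt)
    tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / tot if tot > 0 else 1.0
    aic = _aic(resid, 5)
    return BiExpFit(a=float(popt[0]), b1=float(popt[1]), rate1=float(popt[2]),
                    b2=float(popt[3]), rate2=float(popt[4]), r_squared=r2,
                    converged=converged, aic=aic, delta_aic=aic - mono.aic)


def initial_flux(fit: ExpFit) -> float:
    """J = I_max * tau from a converged mono-exponential fit."""
    if not fit.converged:
        raise ValueError("initial flux requires a converged fit")
    return fit.j


def average_replicates(groups: Dict[str, Iterable[ExpFit]]) -> pd.DataFrame:
    """Average fit parameters and J across biological replicates per sample.

    Each parameter and J are averaged independently, so in general the mean
    J differs from mean(I_max) * mean(tau).  The across-replicate standard
    deviation of J is reported as the error.
    """
    rows = []
    for sample, fits in groups.items():
        fits = list(fits)
        if not fits:
            raise ValueError(f"sample {sample!r} has no fits")
        a = np.array([f.params.a for f in fits])
        imax = np.array([f.params.i_max for f in fits])
        tau = np.array([f.params.tau for f in fits])
        j = np.array([f.j for f in fits])
        rows.append((sample, len(fits), a.mean(), imax.mean(), tau.mean(),
                     j.mean(), j.std(ddof=1) if len(fits) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["sample", "n_replicates", "a", "i_max",
                                       "tau", "j", "j_sd"])
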