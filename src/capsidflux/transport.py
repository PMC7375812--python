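"""Minimal two-parameter free-energy model of large-cargo translocation.

The initial import flux of a cargo impinging on the nuclear pore is

    J = kON * c / (a_Ran + e^dG),    P_tr = 1 / (a_Ran + e^dG)

where dG (in kBT) is the effective free-energy potential of the cargo inside
the pore and a_Ran in [1, 2] encodes RanGTP availability at the nuclear exit
(2 = no RanGTP waiting, 1 = always immediately available).  dG decomposes
into the cost of inserting a particle of radius R into the FG-nucleoporin
assembly and the binding gain of N receptor-bound NLSs:

    dG = F(R) - eps * N,    eps = eps0 * phi

with phi the FG volume fraction (~0.01) and eps0 the bare NTR-FG interaction
energy.  Measured fluxes are normalized so that the model saturation level
1/a_Ran is attainable, inverted to dG values, and fitted with a straight
line in N to extract F(R) (intercept) and eps (-slope) per capsid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

__all__ = [
    "KBT_KCAL_PER_MOL",
    "TransportConfig",
    "EnergyPoint",
    "EnergyFit",
    "normalize_flux",
    "delta_g_from_flux",
    "translocation_probability",
    "fit_energy_model",
    "fit_exclude_zero",
    "predict_flux_curve",
    "epsilon_bare",
    "surface_coverage",
]

#: Display-only conversion: 1 kBT ~ 0.6 kcal/mol at room temperature.
KBT_KCAL_PER_MOL = 0.6


@dataclass(frozen=True)
class TransportConfig:
    a_ran: float = 2.0
    normalization_rule: str = "max_within_ci"
    phi: float = 0.01

    def __post_init__(self) -> None:
        if not (1.0 <= self.a_ran <= 2.0):
            raise ValueError("a_ran must lie in [1, 2]")
        if not (0.0 < self.phi <= 1.0):
            raise ValueError("phi must lie in (0, 1]")
        if self.normalization_rule not in ("max_within_ci", "max"):
            raise ValueError(f"unknown rule {self.normalization_rule!r}")


@dataclass(frozen=True)
class EnergyPoint:
    n_nls: int
    delta_g: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.n_nls < 0:
            raise ValueError("n_nls must be >= 0")
        if not math.isfinite(self.delta_g):
            raise ValueError("delta_g must be finite")


@dataclass(frozen=True)
class EnergyFit:
    """Straight-line fit dG = F(R) - eps*N for one capsid."""

    f_r: float
    eps: float
    se_f: float
    se_eps: float
    capsid: str = ""
    diameter_nm: float = math.nan
    n_points: int = 0
    negative_eps: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "negative_eps", self.eps < 0)

    def predict(self, n) -> np.ndarray:
        return self.f_r - self.eps * np.asarray(n, dtype=float)


def _upper_ci(values: np.ndarray, level: float = 0.95) -> float:
    """Upper bound of the two-sided t confidence interval of the mean."""
    n = values.size
    if n < 2:
        return float(values[0])
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return float(values.mean() + tcrit * values.std(ddof=1) / math.sqrt(n))


def normalize_flux(j_values: Union[Dict[str, Sequence[float]], Sequence[float]],
                   cfg: TransportConfig = TransportConfig(),
                   ) -> Tuple[Dict[str, float], float]:
    """Normalize fluxes by C = a_ran * J*.

    ``j_values`` maps sample id to its replicate-level fluxes (a bare
    sequence is treated as a single sample).  J* is the largest replicate
    flux that does not exceed the 95% upper confidence bound of its own
    sample mean (rule ``max_within_ci``; rule ``max`` takes the global
    maximum).  Returns (sample -> normalized mean flux, C).  The normalized
    values satisfy j_hat <= 1/a_ran, with equality only for the normalizing
    replicate.
    """
    if not isinstance(j_values, dict):
        j_values = {"sample": np.asarray(j_values, float)}
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in j_values.items()}
    pos = [v for arr in arrays.values() for v in arr if v > 0]
    if not pos:
        raise ValueError("no positive fluxes to normalize")
    j_star = -math.inf
    for arr in arrays.values():
        cap = _upper_ci(arr) if cfg.normalization_rule == "max_within_ci" else math.inf
        ok = arr[arr <= cap + 1e-12]
        if ok.size:
            j_star = max(j_star, float(ok.max()))
    c = cfg.a_ran * j_star
    return {k: float(arr.mean()) / c for k, arr in arrays.items()}, c


def delta_g_from_flux(j_hat, a_ran: float = 2.0):
    """Invert the flux law: dG = ln(1/j_hat - a_ran).

    Valid for 0 < j_hat < 1/a_ran; at or above the saturation level the
    inversion diverges to -inf and the point must be excluded instead.
    Preserves the input floating dtype (extended precision passes through).
    """
    if j_hat <= 0:
        raise ValueError("normalized flux must be positive")
    if j_hat >= 1.0 / a_ran:
        warnings.warn(
            f"normalized flux {float(j_hat):.4g} >= saturation 1/a_ran; "
            "dG -> -inf, point should be excluded", RuntimeWarning)
        return -math.inf
    one = np.asarray(1, dtype=np.asarray(j_hat).dtype) \
        if isinstance(j_hat, np.floating) else 1.0
    return np.log(one / j_hat - a_ran)[()] if isinstance(j_hat, np.floating) \
        else math.log(1.0 / j_hat - a_ran)


def translocation_probability(delta_g, a_ran: float = 2.0):
    """P_tr = 1/(a_ran + e^dG): probability that an impinging cargo crosses.

    Preserves the input floating dtype.
    """
    if not (1.0 <= a_ran <= 2.0):
        raise ValueError("a_ran must lie in [1, 2]")
    if isinstance(delta_g, np.floating):
        one = np.asarray(1, dtype=delta_g.dtype)
        return (one / (a_ran + np.exp(delta_g)))[()]
    return 1.0 / (a_ran + math.exp(delta_g))


def _coerce_points(points: Iterable) -> List[EnergyPoint]:
    out = []
    for p in points:
        if isinstance(p, EnergyPoint):
            out.append(p)
        else:
            n, dg = p[0], p[1]
            out.append(EnergyPoint(n_nls=int(n), delta_g=float(dg)))
    return out


def fit_energy_model(points: Iterable, capsid: str = "",
                     diameter_nm: float = math.nan) -> EnergyFit:
    """Ordinary least squares of dG on N: F(R) = intercept, eps = -slope."""
    pts = [p for p in _coerce_points(points) if math.isfinite(p.delta_g)]
    if len(pts) < 3:
        raise ValueError("need at least 3 finite (N, dG) points")
    n = np.array([p.n_nls for p in pts], dtype=float)
    dg = np.array([p.delta_g for p in pts])
    if np.unique(n).size < 2:
        raise ValueError("all N identical: slope unidentifiable")
    res = stats.linregress(n, dg)
    return EnergyFit(f_r=float(res.intercept), eps=-float(res.slope),
                     se_f=float(res.intercept_stderr),
                     se_eps=float(res.stderr), capsid=capsid,
                     diameter_nm=diameter_nm, n_points=len(pts))


def fit_exclude_zero(points: Iterable, capsid: str = "",
                     diameter_nm: float = math.nan) -> EnergyFit:
    """Energy fit restricted to N > 0 (robustness check for the zero point)."""
    pts = [p for p in _coerce_points(points) if p.n_nls > 0]
    if len(pts) == 2:
        # exact line through two points
        (n1, g1), (n2, g2) = (pts[0].n_nls, pts[0].delta_g), (pts[1].n_nls, pts[1].delta_g)
        if n1 == n2:
            raise ValueError("all N identical: slope unidentifiable")
        slope = (g2 - g1) / (n2 - n1)
        return EnergyFit(f_r=g1 - slope * n1, eps=-slope, se_f=0.0, se_eps=0.0,
                         capsid=capsid, diameter_nm=diameter_nm, n_points=2)
    return fit_energy_model(pts, capsid=capsid, diameter_nm=diameter_nm)


def predict_flux_curve(fit: EnergyFit, a_ran: float = 2.0,
                       n_grid: Optional[Sequence[float]] = None) -> np.ndarray:
    """Normalized model flux j_hat(N) = 1/(a_ran + e^(F - eps*N)).

    Saturates to 1/a_ran as N grows (for eps > 0).
    """
    n = np.arange(0, 101) if n_grid is None else np.asarray(n_grid, dtype=float)
    return 1.0 / (a_ran + np.exp(fit.predict(n)))


def epsilon_bare(eps: float, phi: float = 0.01) -> float:
    """Bare NTR-FG interaction energy eps0 = eps / phi (kBT)."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    return eps / phi


def surface_coverage(diameter_nm: float, n_nls: int,
                     footprint_nm2: float = 20.0) -> Tuple[float, float]:
    """Fraction of capsid surface shielded by bound Importins.

    Returns (capped, raw): raw = N * footprint / (pi * d^2); the first value
    is capped at 1.0 for reporting.
    """
    if diameter_nm <= 0:
        raise ValueError("diameter must be positive")
    raw = n_nls * footprint_nm2 / (math.pi * diameter_nm ** 2)
    return min(raw, 1.0), raw
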