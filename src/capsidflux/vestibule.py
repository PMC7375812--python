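"""Heterogeneous-FG-density ("vestibule") extension of the transport model.

The FG-nucleoporin density varies along the pore axis: a low-density cloud
("vestibule") extends into the cytoplasm, narrow medium-density transition
regions flank the pore mouths, and a high-density central barrier fills the
channel.  A cargo with N receptor-bound NLSs sees, in region i with FG
volume fraction phi_i and insertion cost f_i,

    G_i = f_i - eps0 * phi_i * N        (kBT)

with a single bare NTR-FG interaction energy eps0 shared by all capsids.
In the vestibule f = 0 (FG chains and cargo are unconstrained by the pore
scaffold), so a multivalent cargo can accumulate at the nuclear envelope
(Boltzmann weight e^{-G_vestibule} > 1) even when the central barrier blocks
bulk import.

Flux through the in-pore regions is modelled as steady-state 1D diffusion
across the piecewise-constant potential, giving the resistor-like sum

    j_hat = 1 / (a_ran + sum_i w_i e^{G_i})

over in-pore regions with length-fraction weights w_i.  With a single
barrier region (w = 1) this reduces exactly to the minimal model.  The
functional form is this package's modelling choice, isolated behind
``profile_flux`` so it can be swapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FGRegion",
    "FGProfile",
    "default_profile",
    "region_free_energy",
    "profile_flux",
    "vestibule_occupancy",
    "fit_shared_eps0",
    "SharedEps0Fit",
]


@dataclass(frozen=True)
class FGRegion:
    """One axial region of the pore: label, length fraction, FG density, cost."""

    label: str  # vestibule | transition | barrier
    length_fraction: float
    phi: float
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("vestibule", "transition", "barrier"):
            raise ValueError(f"unknown region label {self.label!r}")
        if self.length_fraction <= 0:
            raise ValueError("length_fraction must be > 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.label == "vestibule" and self.f != 0.0:
            raise ValueError("vestibule regions carry no insertion cost (f=0)")


@dataclass(frozen=True)
class FGProfile:
    """Ordered regions from cytoplasmic vestibule to nuclear exit."""

    regions: Tuple[FGRegion, ...]
    diameter_nm: float = math.nan

    def __post_init__(self) -> None:
        total = sum(r.length_fraction for r in self.regions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length fractions must sum to 1, got {total}")
        phis = {lbl: [r.phi for r in self.regions if r.label == lbl]
                for lbl in ("vestibule", "transition", "barrier")}
        lo = max(phis["vestibule"], default=0.0)
        mid_list = phis["transition"]
        hi = min(phis["barrier"], default=math.inf)
        if mid_list and (min(mid_list) < lo or max(mid_list) > hi):
            raise ValueError("densities must be ordered vestibule <= transition <= barrier")
        if not mid_list and phis["barrier"] and lo > hi:
            raise ValueError("densities must be ordered vestibule <= barrier")

    @property
    def in_pore(self) -> Tuple[FGRegion, ...]:
        """Regions inside the pore proper (everything but the vestibule)."""
        return tuple(r for r in self.regions if r.label != "vestibule")

    @property
    def vestibule(self) -> Optional[FGRegion]:
        for r in self.regions:
            if r.label == "vestibule":
                return r
        return None

    @property
    def phi_barrier(self) -> float:
        return max(r.phi for r in self.regions if r.label == "barrier")

    def with_barrier_cost(self, f_barrier: float) -> "FGProfile":
        """Scale in-pore insertion costs as f_i = (phi_i/phi_barrier)*f_barrier."""
        pb = self.phi_barrier
        regions = tuple(
            r if r.label == "vestibule" else replace(r, f=(r.phi / pb) * f_barrier)
            for r in self.regions)
        return FGProfile(regions=regions, diameter_nm=self.diameter_nm)


def default_profile(diameter_nm: float = math.nan) -> FGProfile:
    """Default axial profile: 20% vestibule (phi 0.002, f=0), two 15%
    transitions (phi 0.005) and a 50% central barrier (phi 0.01)."""
    return FGProfile(regions=(
        FGRegion("vestibule", 0.20, 0.002, 0.0),
        FGRegion("transition", 0.15, 0.005, 0.0),
        FGRegion("barrier", 0.50, 0.010, 0.0),
        FGRegion("transition", 0.15, 0.005, 0.0),
    ), diameter_nm=diameter_nm)


def region_free_energy(region: FGRegion, n_nls: float, eps0: float) -> float:
    """G_i = f_i - eps0 * phi_i * N (kBT)."""
    if eps0 < 0:
        raise ValueError("eps0 must be >= 0")
    return region.f - eps0 * region.phi * n_nls


def profile_flux(profile: FGProfile, n_nls, eps0: float,
                 a_ran: float = 2.0) -> np.ndarray:
    """Normalized flux through the piecewise potential.

    j_hat = 1/(a_ran + sum_i w_i e^{G_i}) over in-pore regions, with w_i the
    in-pore length fractions renormalized to sum to 1.  Vectorized over N.
    """
    pore = profile.in_pore
    if not pore:
        raise ValueError("profile has no in-pore regions")
    n = np.asarray(n_nls, dtype=float)
    wsum = sum(r.length_fraction for r in pore)
    acc = np.zeros_like(n, dtype=float)
    for r in pore:
        g = r.f - eps0 * r.phi * n
        acc = acc + (r.length_fraction / wsum) * np.exp(g)
    return 1.0 / (a_ran + acc)


def vestibule_occupancy(profile: FGProfile, n_nls: float, eps0: float) -> float:
    """Relative envelope enrichment: Boltzmann weight e^{-G_vestibule}
    relative to the cytoplasm (G = 0 reference)."""
    v = profile.vestibule
    if v is None:
        raise ValueError("profile contains no vestibule region")
    return math.exp(-region_free_energy(v, n_nls, eps0))


@dataclass
class SharedEps0Fit:
    """Joint fit of one shared eps0 and one barrier cost per capsid."""

    eps0: float
    f_barrier: Dict[str, float]
    residual_joint: float
    residual_independent: float
    converged: bool
    n_points: int
    starts_tried: int = 1


def _independent_residual(datasets, profile, a_ran) -> float:
    """Best per-capsid (eps0_c, f_c) fits; baseline for the joint residual."""
    total = 0.0
    for name, (n, jh) in datasets.items():
        def resid(p):
            prof = profile.with_barrier_cost(p[1])
            return profile_flux(prof, n, p[0], a_ran) - jh
        best = None
        for e0 in (2.0, 6.0, 10.0, 14.0):
            sol = least_squares(resid, [e0, 5.0], bounds=([0, -50], [200, 50]))
            if best is None or sol.cost < best.cost:
                best = sol
        total += 2.0 * best.cost
    return total


def fit_shared_eps0(datasets: Dict[str, Tuple[Sequence[float], Sequence[float]]],
                    profile_template: Optional[FGProfile] = None,
                    a_ran: float = 2.0,
                    starts: Sequence[float] = (2.0, 5.0, 8.0, 12.0, 15.0),
                    ) -> SharedEps0Fit:
    """Fit all capsid flux datasets jointly with one shared eps0.

    ``datasets`` maps capsid name to ``(N_array, j_hat_array)``.  Free
    parameters: the shared eps0 plus one barrier insertion cost per capsid
    (in-pore costs scale with phi_i/phi_barrier).  Multi-start nonlinear
    least squares; also reports the residual of independent per-capsid fits
    for comparison.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 capsid datasets for a shared fit")
    profile = default_profile() if profile_template is None else profile_template
    names = list(datasets)
    data = {k: (np.asarray(v[0], float), np.asarray(v[1], float))
            for k, v in datasets.items()}
    n_points = sum(v[0].size for v in data.values())

    def resid(p):
        eps0 = p[0]
        parts = []
        for i, name in enumerate(names):
            n, jh = data[name]
            prof = profile.with_barrier_cost(p[1 + i])
            parts.append(profile_flux(prof, n, eps0, a_ran) - jh)
        return np.concatenate(parts)

    best = None
    tried = 0
    for e0 in starts:
        tried += 1
        x0 = [e0] + [5.0] * len(names)
        sol = least_squares(resid, x0,
                            bounds=([0] + [-50] * len(names),
                                    [200] + [50] * len(names)))
        if best is None or sol.cost < best.cost:
            best = sol
    joint = 2.0 * best.cost
    indep = _independent_residual(data, profile, a_ran)
    return SharedEps0Fit(
        eps0=float(best.x[0]),
        f_barrier={name: float(best.x[1 + i]) for i, name in enumerate(names)},
        residual_joint=joint, residual_independent=indep,
        converged=bool(best.success), n_points=n_points, starts_tried=tried)
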