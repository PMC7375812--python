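"""Shared kinetic-trace containers.

A nuclear-import experiment yields, for each cellular compartment (nucleus,
nuclear envelope, cytoplasm), the mean cargo fluorescence over time together
with its dispersion across imaged fields of view (FOV).  The saturating
nuclear signal is described by the mono-exponential model

    I(t) = A + I_max * (1 - exp(-tau * t))

with offset ``A`` (accounts for the delay between mixing and the first frame
and for non-specific background), plateau amplitude ``I_max`` and rate
constant ``tau`` (per minute on the native time axis of the traces).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["ExpKineticParams", "IntensityTrace"]


@dataclass(frozen=True)
class ExpKineticParams:
    """Parameters of the mono-exponential accumulation model."""

    a: float
    i_max: float
    tau: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.a):
            raise ValueError("offset A must be finite")
        if not (self.i_max >= 0):
            raise ValueError(f"I_max must be >= 0, got {self.i_max}")
        if not (self.tau >= 0):
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    def evaluate(self, times) -> np.ndarray:
        """Noiseless model value A + I_max*(1 - e^(-tau*t))."""
        t = np.asarray(times, dtype=float)
        return self.a + self.i_max * (-np.expm1(-self.tau * t))

    @property
    def initial_flux(self) -> float:
        """Slope of the accumulation curve at t=0: J = I_max * tau."""
        return self.i_max * self.tau


@dataclass
class IntensityTrace:
    """Time-stamped mean intensities for one compartment.

    ``values`` is the across-FOV mean; ``sd`` the across-FOV standard
    deviation (NaN where unavailable); ``fov_values`` optionally retains the
    per-FOV replicate matrix (n_fov x T).
    """

    times: np.ndarray
    values: np.ndarray
    sd: Optional[np.ndarray] = None
    n_fov: int = 1
    compartment: str = "nucleus"
    seed: Optional[int] = None
    fov_values: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D sequence")
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have matching shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.times.shape:
                raise ValueError("sd must match times in shape")

    def __len__(self) -> int:
        return self.times.size
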