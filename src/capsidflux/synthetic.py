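"""Synthetic ground-truth data for the import-kinetics pipeline.

Everything downstream of the microscope — segmentation, trace extraction,
kinetic fitting, the free-energy models — is testable against data generated
here: noisy mono-exponential traces with across-FOV replication, 3-channel
time-lapse stacks whose compartment geometry matches the mask pipeline's
assumptions, flux-vs-#NLS datasets drawn from the transport model, and the
packaged table of published per-sample fit parameters.

Default acquisition emulates the import assay: frames every 2 minutes over an
80-minute span, with the first frame at t = 2 min because imaging starts
about two minutes after the transport mix is added.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trace import ExpKineticParams, IntensityTrace

__all__ = [
    "TraceNoiseModel",
    "ImageLayout",
    "Table1Fixture",
    "CAPSID_DIAMETERS_NM",
    "default_times",
    "generate_trace",
    "generate_timelapse",
    "simulate_flux_dataset",
    "load_table1_fixture",
]

#: Capsid diameters in nm (from structural characterisation).
CAPSID_DIAMETERS_NM: Dict[str, float] = {
    "MS2^S37P": 17.0,
    "I53-47": 23.0,
    "MS2": 27.0,
    "HBV": 36.0,
}

_TABLE1_SHA256 = "e40a45add8a17185b4d186fd8800140673eb9557f603cb8bd7895e26484cbc4c"
_TABLE1_COLUMNS = [
    "capsid", "sample", "n_dyes", "n_nls", "a", "i_max", "tau", "j", "delta_g",
]


def default_times(interval_min: float = 2.0, span_min: float = 80.0,
                  drop_first: bool = True) -> np.ndarray:
    """Default acquisition time axis in minutes.

    Frames every ``interval_min`` over ``span_min``; the t=0 frame is dropped
    by default to emulate the ~2 min dead time between sample addition and
    the start of imaging.
    """
    t = np.arange(0.0, span_min + 0.5 * interval_min, interval_min)
    return t[1:] if drop_first else t


@dataclass(frozen=True)
class TraceNoiseModel:
    """Additive Gaussian noise applied independently per FOV and time point."""

    sigma: float = 0.0
    n_fov: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_fov < 1:
            raise ValueError(f"n_fov must be >= 1, got {self.n_fov}")


@dataclass(frozen=True)
class ImageLayout:
    """Geometry of a synthetic field of view.

    Nuclei are ellipses ``(cy, cx, ry, rx)`` in pixels.  The ground-truth
    nucleus mask is the ellipse eroded by ``envelope_thickness`` so that the
    envelope ring (the eroded-away rim) is a separate compartment, matching
    the convention of the analysis pipeline.  The cytoplasm is everything
    outside the ellipses by at least ``cytoplasm_margin`` pixels.
    """

    frame_shape: Tuple[int, int] = (128, 128)
    nuclei: Tuple[Tuple[float, float, float, float], ...] = ((64.0, 64.0, 28.0, 24.0),)
    envelope_thickness: int = 3
    cytoplasm_margin: int = 2
    channel_gains: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.envelope_thickness < 1:
            raise ValueError("envelope_thickness must be >= 1")
        h, w = self.frame_shape
        for cy, cx, ry, rx in self.nuclei:
            if not (0 <= cy - ry and cy + ry < h and 0 <= cx - rx and cx + rx < w):
                raise ValueError("nucleus ellipse extends outside the frame")
            if min(ry, rx) <= self.envelope_thickness:
                raise ValueError("nucleus smaller than envelope thickness")

    def ellipse_mask(self) -> np.ndarray:
        """Union of the nuclear ellipses (nucleus + envelope region)."""
        h, w = self.frame_shape
        yy, xx = np.mgrid[0:h, 0:w]
        m = np.zeros((h, w), dtype=bool)
        for cy, cx, ry, rx in self.nuclei:
            m |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        return m

    def ground_truth_masks(self):
        """Disjoint (nucleus, envelope, cytoplasm) boolean masks."""
        from .imaging import MaskSet  # local import to avoid a cycle

        h, w = self.frame_shape
        yy, xx = np.mgrid[0:h, 0:w]
        outer = np.zeros((h, w), dtype=bool)
        inner = np.zeros((h, w), dtype=bool)
        margin = np.zeros((h, w), dtype=bool)
        t = self.envelope_thickness
        g = self.cytoplasm_margin
        for cy, cx, ry, rx in self.nuclei:
            d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
            outer |= d2 <= 1.0
            inner |= ((yy - cy) / (ry - t)) ** 2 + ((xx - cx) / (rx - t)) ** 2 <= 1.0
            margin |= ((yy - cy) / (ry + g)) ** 2 + ((xx - cx) / (rx + g)) ** 2 <= 1.0
        envelope = outer & ~inner
        cytoplasm = ~margin
        return MaskSet(nucleus=inner, envelope=envelope, cytoplasm=cytoplasm)


def generate_trace(params: ExpKineticParams, times: Sequence[float],
                   noise: TraceNoiseModel,
                   compartment: str = "nucleus") -> IntensityTrace:
    """Simulate a noisy mono-exponential intensity trace.

    Each of ``noise.n_fov`` fields of view receives independent additive
    Gaussian noise of standard deviation ``noise.sigma`` at every time point;
    the returned trace carries the across-FOV mean, standard deviation and
    the generating seed.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if t.ndim != 1 or np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("times must be strictly increasing and non-negative")
    mean = params.evaluate(t)
    rng = np.random.default_rng(noise.seed)
    fov = mean[None, :] + rng.normal(0.0, noise.sigma, size=(noise.n_fov, t.size)) \
        if noise.sigma > 0 else np.tile(mean, (noise.n_fov, 1))
    sd = fov.std(axis=0, ddof=1) if noise.n_fov > 1 else np.full(t.size, np.nan)
    return IntensityTrace(times=t, values=fov.mean(axis=0), sd=sd,
                          n_fov=noise.n_fov, compartment=compartment,
                          seed=noise.seed, fov_values=fov)


def generate_timelapse(
    layout: ImageLayout,
    compartment_params: Mapping[str, ExpKineticParams],
    times: Optional[Sequence[float]] = None,
    noise_sigma: float = 0.0,
    poisson: bool = False,
    seed: int = 0,
):
    """Render a 3-channel synthetic time-lapse stack.

    Channel roles: 0 = nuclear stain (nonzero only inside the nuclear
    ellipses), 1 = cytoplasm stain (nonzero only in the cytoplasm), 2 = cargo.
    The cargo channel follows each compartment's kinetic parameters inside
    its ground-truth mask.  Per-pixel noise is additive Gaussian of standard
    deviation ``noise_sigma``, optionally preceded by Poisson shot noise.

    Returns ``(stack, gt_masks, gt_traces, merged)`` where ``merged`` flags
    nuclei whose blurred footprints would overlap.
    """
    from .imaging import FrameStack

    for c in ("nucleus", "envelope", "cytoplasm"):
        if c not in compartment_params:
            raise ValueError(f"compartment_params missing {c!r}")
    t = default_times() if times is None else np.asarray(times, dtype=float)
    gt = layout.ground_truth_masks()
    masks = {"nucleus": gt.nucleus, "envelope": gt.envelope,
             "cytoplasm": gt.cytoplasm}
    h, w = layout.frame_shape
    rng = np.random.default_rng(seed)

    # flag nuclei whose dilated footprints touch (they would merge after blur)
    merged = False
    nuc = layout.nuclei
    for i in range(len(nuc)):
        for k in range(i + 1, len(nuc)):
            dy = nuc[i][0] - nuc[k][0]
            dx = nuc[i][1] - nuc[k][1]
            if math.hypot(dy, dx) < (max(nuc[i][2], nuc[i][3])
                                     + max(nuc[k][2], nuc[k][3]) + 4):
                merged = True

    g1, g2, g3 = layout.channel_gains
    ellipse = layout.ellipse_mask()
    data = np.zeros((t.size, 3, h, w), dtype=float)
    data[:, 0][:, ellipse] = 100.0 * g1
    data[:, 1][:, gt.cytoplasm] = 100.0 * g2
    for c, m in masks.items():
        vals = compartment_params[c].evaluate(t)
        for i in range(t.size):
            data[i, 2][m] = vals[i] * g3
    if poisson:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)

    stack = FrameStack(data=data, times=t,
                       channel_roles=("nucleus", "cytoplasm", "cargo"))
    traces = {
        c: IntensityTrace(times=t, values=compartment_params[c].evaluate(t),
                          compartment=c, seed=seed)
        for c in masks
    }
    return stack, gt, traces, merged


def simulate_flux_dataset(f_r: float, eps: float, a_ran: float,
                          n_values: Sequence[int], noise_cv: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Draw a normalized flux-vs-#NLS dataset from the minimal model.

    Noiseless fluxes follow J(N) = 1/(a_ran + exp(F_R - eps*N)); noise is
    multiplicative log-normal with coefficient of variation ``noise_cv``,
    emulating run-to-run variability of measured initial fluxes.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0 (binding energy gain)")
    if not (1.0 <= a_ran <= 2.0):
        raise ValueError("a_ran must lie in [1, 2]")
    n = np.asarray(n_values)
    if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
        raise ValueError("n_values must be non-negative integers")
    j = 1.0 / (a_ran + np.exp(f_r - eps * n.astype(float)))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        s = math.sqrt(math.log1p(noise_cv ** 2))
        j = j * rng.lognormal(-0.5 * s * s, s, size=j.size)
    return pd.DataFrame({"n_nls": n, "j": j})


@dataclass(frozen=True)
class Table1Fixture:
    """The published per-sample kinetic fit table, packaged as a fixture."""

    frame: pd.DataFrame = field(repr=False)

    @property
    def rows(self):
        return list(self.frame.itertuples(index=False))

    def capsid(self, name: str) -> pd.DataFrame:
        sub = self.frame[self.frame["capsid"] == name]
        if sub.empty:
            raise KeyError(f"unknown capsid {name!r}")
        return sub.reset_index(drop=True)

    @property
    def capsids(self):
        return list(dict.fromkeys(self.frame["capsid"]))


def load_table1_fixture() -> Table1Fixture:
    """Load and checksum-validate the packaged kinetic-fit table (27 rows)."""
    ref = resources.files("capsidflux.data").joinpath("table1.csv")
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:  # pragma: no cover
        raise FileNotFoundError("packaged table1.csv fixture is missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError("table1.csv fixture is corrupt (checksum mismatch)")
    import io

    df = pd.read_csv(io.BytesIO(raw))
    if list(df.columns) != _TABLE1_COLUMNS or len(df) != 27:
        raise ValueError("table1.csv fixture has unexpected layout")
    return Table1Fixture(frame=df)
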