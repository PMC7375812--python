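"""Compartment segmentation and trace extraction from time-lapse stacks.

Re-implements the reference-channel mask pipeline: the nuclear-stain and
cytoplasm-stain channels are Gaussian-blurred and thresholded; the nuclear
mask is eroded (three times by default) to keep nucleoplasmic signal clear of
the rim; the nuclear-envelope mask is the difference between the pre-erosion
and eroded nuclear masks; the cytoplasm mask is the thresholded cytoplasm
channel minus the pre-erosion nuclear mask.  The masks are then applied to
the cargo channel to obtain per-compartment mean-intensity traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects

from .trace import IntensityTrace

__all__ = [
    "FrameStack",
    "MaskSet",
    "SegmentationConfig",
    "SegmentationError",
    "segment_compartments",
    "segment_stack",
    "extract_traces",
    "estimate_background",
    "read_stack",
    "write_masks",
    "write_stack",
    "write_traces_csv",
]

COMPARTMENTS = ("nucleus", "envelope", "cytoplasm")

# 3x3 full-connectivity structuring element for erosion
_SQUARE3 = np.ones((3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when a reference channel yields no usable mask."""


@dataclass
class FrameStack:
    """A T x C x H x W stack with named channel roles."""

    data: np.ndarray
    times: np.ndarray
    channel_roles: Tuple[str, str, str] = ("nucleus", "cytoplasm", "cargo")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be T x C x H x W")
        if self.data.shape[0] != self.times.size or self.data.shape[0] < 1:
            raise ValueError("time axis mismatch")
        roles = set(self.channel_roles)
        if roles != {"nucleus", "cytoplasm", "cargo"}:
            raise ValueError("channel roles must be nucleus/cytoplasm/cargo")
        if len(self.channel_roles) != self.data.shape[1]:
            raise ValueError("channel count mismatch")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    def channel(self, role: str) -> np.ndarray:
        """T x H x W view of the channel with the given role."""
        return self.data[:, self.channel_roles.index(role)]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class MaskSet:
    """Pairwise-disjoint binary masks for the three compartments."""

    nucleus: np.ndarray
    envelope: np.ndarray
    cytoplasm: np.ndarray

    def __post_init__(self) -> None:
        for name in COMPARTMENTS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {getattr(self, n).shape for n in COMPARTMENTS}
        if len(shapes) != 1:
            raise ValueError("mask shapes differ")
        if (np.any(self.nucleus & self.envelope)
                or np.any(self.nucleus & self.cytoplasm)
                or np.any(self.envelope & self.cytoplasm)):
            raise ValueError("compartment masks must be pairwise disjoint")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in COMPARTMENTS:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def union(self) -> np.ndarray:
        return self.nucleus | self.envelope | self.cytoplasm


@dataclass(frozen=True)
class SegmentationConfig:
    blur_sigma: float = 1.0
    threshold_method: str = "otsu"
    erosion_iterations: int = 3
    min_object_area: int = 64
    static_masks: bool = False  # segment frame 0 only and reuse

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")
        if self.erosion_iterations < 0:
            raise ValueError("erosion_iterations must be >= 0")
        if self.threshold_method not in ("otsu", "mean"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


def _threshold(img: np.ndarray, method: str) -> float:
    if img.max() <= img.min():
        raise SegmentationError("no objects segmented: channel is constant")
    if method == "otsu":
        return float(threshold_otsu(img))
    return float(img.mean())


def _binarize(channel: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    img = gaussian(channel, sigma=cfg.blur_sigma, preserve_range=True) \
        if cfg.blur_sigma > 0 else channel
    mask = img > _threshold(img, cfg.threshold_method)
    if cfg.min_object_area > 0:
        # removes objects of size <= max_size, i.e. keeps >= min_object_area
        mask = remove_small_objects(mask, max_size=cfg.min_object_area - 1)
    return mask


def segment_compartments(frame: np.ndarray,
                         cfg: SegmentationConfig = SegmentationConfig(),
                         channel_roles: Sequence[str] = ("nucleus", "cytoplasm", "cargo"),
                         ) -> MaskSet:
    """Build the three compartment masks from one C x H x W frame.

    The nucleus mask is the blurred, thresholded, size-filtered nuclear
    channel eroded ``cfg.erosion_iterations`` times with a 3x3 square; the
    envelope is the eroded-away rim; the cytoplasm is the thresholded
    cytoplasm channel minus the pre-erosion nuclear mask.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3:
        raise ValueError("frame must be C x H x W")
    roles = list(channel_roles)
    nuc_raw = frame[roles.index("nucleus")]
    cyt_raw = frame[roles.index("cytoplasm")]

    if not np.any(nuc_raw):
        raise SegmentationError("no objects segmented: nuclear channel is all zero")
    if not np.any(cyt_raw):
        raise SegmentationError("no objects segmented: cytoplasm channel is all zero")

    pre = _binarize(nuc_raw, cfg)
    if not pre.any():
        raise SegmentationError("nuclear mask empty after thresholding/size filter")
    eroded = pre
    if cfg.erosion_iterations > 0:
        eroded = ndi.binary_erosion(pre, structure=_SQUARE3,
                                    iterations=cfg.erosion_iterations)
    if not eroded.any():
        raise SegmentationError(
            f"nuclear mask empty after {cfg.erosion_iterations} erosions")
    envelope = pre & ~eroded
    cyt = _binarize(cyt_raw, cfg) & ~pre
    return MaskSet(nucleus=eroded, envelope=envelope, cytoplasm=cyt)


def segment_stack(stack: FrameStack,
                  cfg: SegmentationConfig = SegmentationConfig()) -> List[MaskSet]:
    """Per-frame masks (or one reused mask set when ``cfg.static_masks``)."""
    if cfg.static_masks:
        m = segment_compartments(stack.data[0], cfg, stack.channel_roles)
        return [m] * len(stack)
    return [segment_compartments(stack.data[i], cfg, stack.channel_roles)
            for i in range(len(stack))]


def extract_traces(stack: FrameStack,
                   masks: Union[MaskSet, Sequence[MaskSet]],
                   ) -> Dict[str, IntensityTrace]:
    """Mean cargo intensity per compartment and frame.

    ``masks`` may be a single static MaskSet or one per frame.  An empty mask
    yields NaN for that frame (missing, not zero).
    """
    per_frame = [masks] * len(stack) if isinstance(masks, MaskSet) else list(masks)
    if len(per_frame) != len(stack):
        raise ValueError("need one MaskSet per frame")
    cargo = stack.channel("cargo")
    if per_frame[0].nucleus.shape != stack.frame_shape:
        raise ValueError("mask shape does not match frame shape")
    out: Dict[str, IntensityTrace] = {}
    for comp in COMPARTMENTS:
        vals = np.empty(len(stack))
        for i, m in enumerate(per_frame):
            sel = m[comp]
            vals[i] = cargo[i][sel].mean() if sel.any() else np.nan
        out[comp] = IntensityTrace(times=stack.times, values=vals,
                                   compartment=comp)
    return out


def estimate_background(stack: FrameStack,
                        masks: Union[MaskSet, Sequence[MaskSet]]) -> np.ndarray:
    """Mean cargo intensity outside all masks, per frame (NaN if none)."""
    per_frame = [masks] * len(stack) if isinstance(masks, MaskSet) else list(masks)
    cargo = stack.channel("cargo")
    out = np.empty(len(stack))
    for i, m in enumerate(per_frame):
        outside = ~m.union
        out[i] = cargo[i][outside].mean() if outside.any() else np.nan
    return out


def read_stack(path: Union[str, Path],
               times: Optional[Sequence[float]] = None,
               channel_roles: Tuple[str, str, str] = ("nucleus", "cytoplasm", "cargo"),
               ) -> FrameStack:
    """Read a T x C x H x W (or C x H x W) TIFF stack."""
    import tifffile

    data = np.asarray(tifffile.imread(str(path)), dtype=float)
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise ValueError(f"expected a 3- or 4-D TIFF, got shape {data.shape}")
    if times is None:
        times = 2.0 * (1 + np.arange(data.shape[0]))
    return FrameStack(data=data, times=np.asarray(times, float),
                      channel_roles=channel_roles)


def write_stack(stack: FrameStack, path: Union[str, Path]) -> None:
    """Write a stack as a multi-page float32 TIFF (T x C x H x W)."""
    import tifffile

    tifffile.imwrite(str(path), stack.data.astype(np.float32),
                     photometric="minisblack")


def write_masks(masks: MaskSet, path: Union[str, Path]) -> None:
    """Write a MaskSet as one labelled PNG (0 bg, 1 nucleus, 2 envelope,
    3 cytoplasm)."""
    import imageio.v3 as iio

    label = np.zeros(masks.nucleus.shape, dtype=np.uint8)
    for value, comp in enumerate(COMPARTMENTS, start=1):
        label[masks[comp]] = value
    iio.imwrite(str(path), label)


def write_traces_csv(traces: Dict[str, IntensityTrace],
                     path: Union[str, Path], position: str = "pos0") -> pd.DataFrame:
    """Write traces as tidy CSV (position, time_min, compartment, ...)."""
    rows = []
    for comp, tr in traces.items():
        sd = tr.sd if tr.sd is not None else np.full(len(tr), np.nan)
        for t, v, s in zip(tr.times, tr.values, sd):
            rows.append((position, t, comp, v, s, tr.n_fov))
    df = pd.DataFrame(rows, columns=["position", "time_min", "compartment",
                                     "mean_intensity", "sd", "n_fov"])
    df.to_csv(path, index=False)
    return df
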