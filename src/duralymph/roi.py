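"""ROI-based lymphatic signal extraction from a dynamic FLAIR series.

A rectangular ROI is centered at a user-selected voxel over the inferior
dural lymphatic vessel and replicated on every slice.  The lymphatic signal
at each time point is the robust maximum (98th percentile, linear
interpolation between order statistics) of all pooled ROI voxels, normalized
to the median brain signal of the precontrast volume.

Voxel coordinates are 0-based ``(slice, row, col)`` throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

#: Default ROI size (rows x cols) per slice: a vessel-scale window at
#: half-millimetre in-plane resolution.
DEFAULT_ROI_HEIGHT = 3
DEFAULT_ROI_WIDTH = 5

ROBUST_PERCENTILE = 98.0


@dataclass(frozen=True)
class ROISpec:
    """A rectangular per-slice ROI window, replicated on all slices.

    ``rows`` and ``cols`` are half-open index ranges (lo, hi) already
    clipped to the image bounds.
    """

    center: tuple[int, int, int]
    rows: tuple[int, int]
    cols: tuple[int, int]
    applies_to_all_slices: bool = True

    def __post_init__(self):
        if self.rows[0] >= self.rows[1] or self.cols[0] >= self.cols[1]:
            raise InputError("ROI clipped to image bounds is empty")


@dataclass(frozen=True)
class TimeIntensityCurve:
    """Normalized lymphatic signal versus acquisition time.

    ``times`` are minutes with ``times[0] == 0`` (precontrast defines S_0);
    ``signal`` is in units of the precontrast brain median.
    """

    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, float)
        s = np.asarray(self.signal, float)
        if t.ndim != 1 or t.shape != s.shape or t.size < 2:
            raise InputError("times/signal must be matching 1-D arrays of length >= 2")
        if t[0] != 0:
            raise InputError("times[0] must be 0 (precontrast)")
        if np.any(np.diff(t) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise InputError("signal must be finite and nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)

    @property
    def s0(self) -> float:
        return float(self.signal[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "signal_norm": self.signal})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TimeIntensityCurve":
        return cls(
            times=frame["time_min"].to_numpy(float),
            signal=frame["signal_norm"].to_numpy(float),
        )


def place_roi(
    seed_voxel: tuple[int, int, int],
    height: int = DEFAULT_ROI_HEIGHT,
    width: int = DEFAULT_ROI_WIDTH,
    image_shape: tuple[int, int, int] = (10, 256, 256),
) -> ROISpec:
    """Center a height x width window at the seed voxel, on every slice.

    Odd sizes are symmetric about the seed; even sizes extend one extra
    voxel toward increasing index.  The window is clipped at image edges.
    """
    if height < 1 or width < 1:
        raise InputError("ROI height and width must be >= 1")
    sl, row, col = (int(v) for v in seed_voxel)
    shape = tuple(int(v) for v in image_shape)
    if not (0 <= sl < shape[0] and 0 <= row < shape[1] and 0 <= col < shape[2]):
        raise InputError(f"seed voxel {seed_voxel} outside image of shape {shape}")
    r_lo = max(row - (height - 1) // 2, 0)
    r_hi = min(row + height // 2 + 1, shape[1])
    c_lo = max(col - (width - 1) // 2, 0)
    c_hi = min(col + width // 2 + 1, shape[2])
    return ROISpec(center=(sl, row, col), rows=(r_lo, r_hi), cols=(c_lo, c_hi))


def robust_max(values) -> float:
    """98th percentile with linear interpolation at position 0.98 * (n - 1)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise InputError("robust_max of an empty collection")
    if not np.all(np.isfinite(v)):
        raise InputError("robust_max requires finite values")
    return float(np.percentile(v, ROBUST_PERCENTILE))


def brain_reference(precontrast_volume: np.ndarray, brain_mask: np.ndarray) -> float:
    """Median in-mask intensity of the precontrast volume.

    Even-count medians are the mean of the two central order statistics.
    """
    vol = np.asarray(precontrast_volume, float)
    mask = np.asarray(brain_mask, bool)
    if vol.shape != mask.shape:
        raise InputError("precontrast volume and mask shapes differ")
    if not mask.any():
        raise InputError("brain mask is empty")
    return float(np.median(vol[mask]))


def extract_curve(series, roi: ROISpec, mask: np.ndarray | None = None) -> TimeIntensityCurve:
    """Pool ROI voxels across all slices per time point, take the robust
    maximum, and normalize by the precontrast brain median.

    ``series`` is a :class:`~duralymph.phantom.DynamicSeries` (or anything
    with ``data`` of shape (T, slices, rows, cols), ``times`` and
    ``brain_mask``).  The ROI may legitimately fall outside the brain mask
    (the vessel is extra-parenchymal); this only triggers a warning.
    """
    data = np.asarray(series.data, float)
    times = np.asarray(series.times, float)
    if data.ndim != 4:
        raise InputError("series.data must be 4-D (time, slice, row, col)")
    if data.shape[0] != times.size:
        raise InputError("series time axis does not match its time metadata")
    if times.size < 2:
        raise InputError("need at least 2 time points (precontrast + postcontrast)")
    if mask is None:
        mask = series.brain_mask
    mask = np.asarray(mask, bool)

    (r_lo, r_hi), (c_lo, c_hi) = roi.rows, roi.cols
    roi_mask = np.zeros(data.shape[1:], dtype=bool)
    roi_mask[:, r_lo:r_hi, c_lo:c_hi] = True
    if not (roi_mask & mask).any():
        warnings.warn(
            "ROI lies entirely outside the brain mask (expected for an "
            "extra-parenchymal vessel); proceeding",
            stacklevel=2,
        )
    reference = brain_reference(data[0], mask)
    if reference <= 0:
        raise InputError("precontrast brain median is not positive")
    pooled = data[:, :, r_lo:r_hi, c_lo:c_hi].reshape(data.shape[0], -1)
    signal = np.percentile(pooled, ROBUST_PERCENTILE, axis=1) / reference
    return TimeIntensityCurve(times=times, signal=signal)
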