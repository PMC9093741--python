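"""Photometric calibration and ROI trace handling.

Raw camera counts from a scientific-CMOS sensor are converted to light
power (femtowatts) using the sensor's full-well capacity, so that
recordings acquired at different frame rates and with different
expression levels can be compared on a common physical scale.  The
mapping assumes a linear sensor whose maximal digital value corresponds
to a full well of electrons::

    electrons = counts * full_well / digital_max
    power [W] = electrons * 1.6e-19 [J] * frame_rate [1/s]

The electron energy constant is kept at the rounded value 1.6e-19 J to
preserve the numeric scale of the original calibration (2880 fW at
digital maximum for a 600,000 e- well sampled at 30 fps).

Baseline fluorescence F0 is the minimum of the 500 ms window preceding
an event onset, and DFF is the usual (F - F0)/F0.  No background
subtraction is applied anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "CameraModel",
    "FluorescenceTrace",
    "RoiMask",
    "SaturationError",
    "counts_to_power",
    "power_to_electrons",
    "electrons_to_counts",
    "extract_roi_trace",
    "baseline_f0",
    "dff",
]

#: Electron charge-energy constant [J], rounded as used by the calibration.
ELECTRON_ENERGY_J = 1.6e-19

VALID_UNITS = ("counts", "fW", "dff", "mV")


class SaturationError(ValueError):
    """Raised when digital counts exceed the sensor's digital maximum."""


@dataclass(frozen=True)
class CameraModel:
    """Linear sCMOS camera description.

    Parameters
    ----------
    full_well : float
        Full-well capacity in electrons.
    dark_noise : float
        RMS dark/read noise in electrons.
    digital_max : int
        Largest representable digital count (ADC ceiling).
    electron_energy_j : float
        Energy constant used for the photometric scale, in joules.
    frame_rate : float
        Nominal acquisition rate in frames/s (used by the simulator;
        conversions use the frame rate carried by each trace).
    """

    full_well: float = 600_000.0
    dark_noise: float = 130.0
    digital_max: int = 65_535
    electron_energy_j: float = ELECTRON_ENERGY_J
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        if not (self.full_well > self.dark_noise > 0):
            raise ValueError("require full_well > dark_noise > 0")
        if self.digital_max <= 0:
            raise ValueError("digital_max must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def electrons_per_count(self) -> float:
        return self.full_well / self.digital_max

    def full_well_power_fw(self, frame_rate: Optional[float] = None) -> float:
        """Light power [fW] that fills the well every frame."""
        fr = self.frame_rate if frame_rate is None else frame_rate
        return self.full_well * self.electron_energy_j * fr * 1e15


@dataclass
class FluorescenceTrace:
    """Per-ROI fluorescence time series.

    ``unit`` flags the physical scale of ``values``: raw digital
    ``counts``, calibrated ``fW``, or baseline-normalized ``dff``.
    """

    values: np.ndarray
    frame_rate: float
    roi_id: str | int = 0
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def rate(self) -> float:
        """Sampling rate alias shared with voltage traces."""
        return self.frame_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate

    def with_values(self, values: np.ndarray, unit: Optional[str] = None) -> "FluorescenceTrace":
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else unit)


@dataclass
class RoiMask:
    """Region of interest as a boolean pixel mask.

    ``pixel_size_um`` converts pixel geometry to micrometres; ``area``
    and ``centroid`` are derived from the mask if not given.
    """

    mask: np.ndarray
    pixel_size_um: float = 1.0
    roi_id: str | int = 0
    area: float = field(default=0.0)
    centroid: tuple[float, float] = field(default=(np.nan, np.nan))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D image")
        n = int(self.mask.sum())
        if n == 0:
            raise ValueError("ROI mask is empty")
        if self.area == 0.0:
            self.area = n * self.pixel_size_um**2
        if np.isnan(self.centroid[0]):
            rr, cc = np.nonzero(self.mask)
            self.centroid = (float(rr.mean()) * self.pixel_size_um,
                             float(cc.mean()) * self.pixel_size_um)


def counts_to_power(trace: FluorescenceTrace, camera: CameraModel) -> FluorescenceTrace:
    """Convert a raw-count trace to light power in femtowatts.

    Linear in both counts and frame rate.  Raises
    :class:`SaturationError` if any sample exceeds the digital maximum.
    """
    if trace.unit != "counts":
        raise ValueError(f"expected a counts trace, got unit={trace.unit!r}")
    if np.any(trace.values > camera.digital_max):
        raise SaturationError(
            f"{int(np.sum(trace.values > camera.digital_max))} samples exceed "
            f"digital_max={camera.digital_max} (sensor saturation)")
    if np.any(trace.values < 0):
        raise ValueError("counts must be non-negative")
    electrons = trace.values * camera.electrons_per_count
    power_w = electrons * camera.electron_energy_j * trace.frame_rate
    return trace.with_values(power_w * 1e15, unit="fW")


def power_to_electrons(power_fw: np.ndarray, camera: CameraModel, frame_rate: float) -> np.ndarray:
    """Expected electrons collected per frame for a given light power [fW]."""
    return np.asarray(power_fw) * 1e-15 / (camera.electron_energy_j * frame_rate)


def electrons_to_counts(electrons: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Quantize electrons to clipped digital counts (rounding ADC)."""
    counts = np.rint(np.asarray(electrons) / camera.electrons_per_count)
    return np.clip(counts, 0, camera.digital_max)


def extract_roi_trace(image_series: np.ndarray, roi: RoiMask,
                      frame_rate: float = 30.0) -> FluorescenceTrace:
    """Average all pixels inside the ROI for each frame.

    ``image_series`` has shape (frames, rows, cols); the result is the
    per-frame arithmetic mean over the ROI pixels, in raw counts.
    """
    stack = np.asarray(image_series)
    if stack.ndim != 3:
        raise ValueError("image_series must have shape (frames, rows, cols)")
    if roi.mask.shape != stack.shape[1:]:
        raise ValueError("ROI mask shape does not match image frames")
    values = stack[:, roi.mask].mean(axis=1)
    return FluorescenceTrace(values, frame_rate=frame_rate, roi_id=roi.roi_id,
                             unit="counts")


def baseline_f0(trace: FluorescenceTrace, onset: int, window_ms: float = 500.0) -> float:
    """Baseline F0: minimum over the ``window_ms`` window before ``onset``.

    The window is the half-open frame range ``[onset - n, onset)``; when
    the onset sits closer to the recording start than the window length,
    the minimum is taken over the available prefix.  An onset at frame 0
    leaves no prefix and is an error.
    """
    if onset < 0:
        raise ValueError("onset must be non-negative")
    n = max(1, int(round(window_ms / 1000.0 * trace.frame_rate)))
    lo = max(0, onset - n)
    window = trace.values[lo:onset]
    if window.size == 0:
        raise ValueError("no samples before onset to estimate a baseline")
    return float(window.min())


def dff(trace: FluorescenceTrace, f0: float) -> FluorescenceTrace:
    """Baseline-normalized trace (F - F0)/F0."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    return trace.with_values((trace.values - f0) / f0, unit="dff")
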