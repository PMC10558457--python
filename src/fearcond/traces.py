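"""Trace-level preprocessing.

Background subtraction from ring-shaped background ROIs, dF/F computation,
within-day z-normalization, and event binarization/binning — the standard
path from raw somatic fluorescence to the z-scored traces and 1-s binary
rasters consumed by the decoding and network modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PixelMovie",
    "RoiSet",
    "TraceMatrix",
    "EventRaster",
    "build_background_rois",
    "subtract_background",
    "compute_dff",
    "znormalize",
    "binarize_events",
]


@dataclass
class PixelMovie:
    """Raw movie [frames x height x width] at a fixed frame rate."""

    intensities: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise ValueError("movie must be [frames x h x w] with >= 1 frame")
        if not np.isfinite(self.intensities).all():
            raise ValueError("movie contains non-finite values")


@dataclass
class RoiSet:
    """Neuronal ROI masks and (derived) background-ring masks.

    ``padded_pixels`` optionally flags pixels that were artificially filled
    at any time point (e.g. border fill from motion registration); such
    pixels are never admitted into a background ring.
    """

    masks: list[np.ndarray]
    background_masks: list[np.ndarray] = field(default_factory=list)
    padded_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        for i, m in enumerate(self.masks):
            if not np.asarray(m).any():
                raise ValueError(f"neuronal ROI {i} is empty")

    @property
    def n_rois(self) -> int:
        return len(self.masks)


@dataclass
class TraceMatrix:
    """Activity [neurons x frames] with unit bookkeeping.

    ``unit`` moves only forward along raw -> dff -> z; ``frame_day`` gives
    the recording day of every frame so day-scoped operations (z-scoring,
    dF/F baselines) can split correctly.
    """

    values: np.ndarray
    unit: str
    frame_rate_hz: float
    frame_day: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be [neurons x frames]")
        if self.unit not in ("raw", "dff", "z"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.frame_day is None:
            self.frame_day = np.zeros(self.values.shape[1], dtype=int)
        self.frame_day = np.asarray(self.frame_day)
        if self.frame_day.shape != (self.values.shape[1],):
            raise ValueError("frame_day must have one entry per frame")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def day_slice(self, day: int) -> np.ndarray:
        return self.values[:, self.frame_day == day]

    @classmethod
    def from_days(cls, per_day: dict[int, np.ndarray], unit: str, frame_rate_hz: float) -> "TraceMatrix":
        days = sorted(per_day)
        values = np.concatenate([per_day[d] for d in days], axis=1)
        frame_day = np.concatenate([np.full(per_day[d].shape[1], d, dtype=int) for d in days])
        return cls(values=values, unit=unit, frame_rate_hz=frame_rate_hz, frame_day=frame_day)


@dataclass
class EventRaster:
    """Binary activity [neurons x bins] at a fixed bin size."""

    active: np.ndarray
    bin_size_s: float = 1.0

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active)
        if self.bin_size_s <= 0:
            raise ValueError("bin_size_s must be > 0")
        if not np.isin(self.active, (0, 1)).all():
            raise ValueError("raster must be binary")


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------

def _pixel_series(movie: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return movie[:, mask]  # [frames x pixels]


def build_background_rois(rois: RoiSet, movie: PixelMovie, *, gap_px: int = 2,
                          max_gap_px: int = 5, max_width_px: int = 35,
                          min_pixels: int = 20, sd_factor: float = 2.0) -> RoiSet:
    """Construct a ring-shaped background ROI around each neuronal ROI.

    The ring starts ``gap_px``..``max_gap_px`` outside the ROI border and is
    widened (up to ``max_width_px``) until at least ``min_pixels`` pixels
    survive three exclusions: membership in any neuronal ROI, artificial
    padding at any time point, and pixels whose time series exceeds the ROI
    mean series by more than ``sd_factor`` standard deviations of their
    pointwise difference at any time point.
    """
    mov = movie.intensities
    any_roi = np.zeros(mov.shape[1:], dtype=bool)
    for m in rois.masks:
        any_roi |= m
    forbidden = any_roi.copy()
    if rois.padded_pixels is not None:
        forbidden |= rois.padded_pixels
    bg_masks = []
    for i, mask in enumerate(rois.masks):
        roi_series = _pixel_series(mov, mask).mean(axis=1)
        found = None
        for gap in range(gap_px, max_gap_px + 1):
            for width in range(3, max_width_px + 1):
                inner = ndimage.binary_dilation(mask, iterations=gap)
                outer = ndimage.binary_dilation(mask, iterations=gap + width)
                ring = outer & ~inner & ~forbidden
                if ring.sum() < min_pixels:
                    continue
                px = _pixel_series(mov, ring)  # [frames x pixels]
                diff = px - roi_series[:, None]
                sd = diff.std(axis=0)
                with np.errstate(invalid="ignore"):
                    bad = (diff > sd_factor * sd[None, :]).any(axis=0) & (sd > 0)
                keep = ~bad
                if keep.sum() >= min_pixels:
                    full = np.zeros_like(ring)
                    flat = np.flatnonzero(ring.ravel())[keep]
                    full.ravel()[flat] = True
                    found = full
                    break
            if found is not None:
                break
        if found is None:
            raise ValueError(f"no background ring with >= {min_pixels} pixels for ROI {i}")
        bg_masks.append(found)
    return RoiSet(masks=rois.masks, background_masks=bg_masks, padded_pixels=rois.padded_pixels)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter windows at ends)."""
    window = min(window, x.size)
    if window <= 1:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def subtract_background(movie: PixelMovie, rois: RoiSet, *,
                        ma_window_s: float = 10.0) -> TraceMatrix:
    """ROI pixel-mean series minus the smoothed background-ring series.

    The background series is smoothed with a centered moving average
    (default 10 s) before subtraction so that frame-to-frame background
    noise is not injected into the neuronal trace.
    """
    if len(rois.background_masks) != len(rois.masks):
        rois = build_background_rois(rois, movie)
    window = max(1, int(round(ma_window_s * movie.frame_rate_hz)))
    out = np.empty((rois.n_rois, movie.intensities.shape[0]))
    for i, (mask, bg) in enumerate(zip(rois.masks, rois.background_masks)):
        roi_series = _pixel_series(movie.intensities, mask).mean(axis=1)
        bg_series = _pixel_series(movie.intensities, bg).mean(axis=1)
        out[i] = roi_series - _moving_average(bg_series, window)
    return TraceMatrix(values=out, unit="raw", frame_rate_hz=movie.frame_rate_hz)


# ---------------------------------------------------------------------------
# dF/F, z-normalization, event binarization
# ---------------------------------------------------------------------------

def compute_dff(trace: TraceMatrix, *, f0_percentile: float = 20.0,
                f0: np.ndarray | None = None) -> TraceMatrix:
    """(F - F0) / F0 per neuron, per day.

    F0 defaults to the 20th percentile of the raw trace within each day — a
    baseline robust to sparse transients.  An explicit per-neuron ``f0``
    (constant across days) may be supplied instead.
    """
    if trace.unit != "raw":
        raise ValueError(f"compute_dff expects unit='raw', got {trace.unit!r}")
    out = np.empty_like(trace.values)
    for day in np.unique(trace.frame_day):
        cols = trace.frame_day == day
        block = trace.values[:, cols]
        base = np.percentile(block, f0_percentile, axis=1) if f0 is None else np.asarray(f0, float)
        bad = np.flatnonzero(base <= 0)
        if bad.size:
            raise ValueError(f"non-positive F0 baseline for neuron(s) {bad.tolist()} on day {day}")
        out[:, cols] = (block - base[:, None]) / base[:, None]
    return TraceMatrix(values=out, unit="dff", frame_rate_hz=trace.frame_rate_hz,
                       frame_day=trace.frame_day)


def znormalize(trace: TraceMatrix) -> TraceMatrix:
    """Z-score each neuron within each day (population SD, ddof=0).

    Scoping follows the same-animal / same-day convention: a trace spanning
    multiple days is normalized independently within each day.  Idempotent.
    """
    if trace.unit not in ("dff", "z"):
        raise ValueError(f"znormalize expects unit 'dff' (or 'z'), got {trace.unit!r}")
    out = np.empty_like(trace.values)
    for day in np.unique(trace.frame_day):
        cols = trace.frame_day == day
        block = trace.values[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() == 0)
        if bad.size:
            raise ValueError(f"zero-SD trace for neuron(s) {bad.tolist()} on day {day}")
        out[:, cols] = (block - mu) / sd
    return TraceMatrix(values=out, unit="z", frame_rate_hz=trace.frame_rate_hz,
                       frame_day=trace.frame_day)


def binarize_events(values: np.ndarray | TraceMatrix, *, threshold_sd: float = 2.0,
                    bin_s: float = 1.0, frame_rate_hz: float | None = None) -> EventRaster:
    """Threshold at mean + ``threshold_sd``*SD per neuron and bin.

    A bin is active if any constituent frame crossed the threshold (the
    any-frame rule preserves sparse events at 1-s bins).  Accepts either a
    TraceMatrix (e.g. inferred spike probabilities) or a plain array with an
    explicit frame rate.
    """
    if isinstance(values, TraceMatrix):
        frame_rate_hz = values.frame_rate_hz
        arr = values.values
    else:
        arr = np.asarray(values, dtype=float)
        if frame_rate_hz is None:
            raise ValueError("frame_rate_hz required for array input")
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite values")
    frames_per_bin = bin_s * frame_rate_hz
    if frames_per_bin < 1.0:
        raise ValueError("bin_s smaller than the frame period")
    fpb = int(round(frames_per_bin))
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    hot = arr > mu + threshold_sd * sd
    n, nf = hot.shape
    n_bins = nf // fpb
    binned = hot[:, : n_bins * fpb].reshape(n, n_bins, fpb).any(axis=2)
    return EventRaster(active=binned.astype(np.int8), bin_size_s=bin_s)
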