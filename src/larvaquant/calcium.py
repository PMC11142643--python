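"""Calcium-trace metrics: dF/F normalization, evoked-response AUC ratios,
peak detection, onset, response duration, and amplitude histograms.

Conventions
-----------
* dF/F is a global min-max normalization of the whole recording,
  ``(F_i - F_min) / (F_max - F_min)``, stored as a fraction in [0, 1];
  percent dF/F is a display scale only.
* Peak criteria mirror MATLAB ``findpeaks`` semantics: topographic prominence
  on the normalized scale (0.3 = 30 %dF/F) and width measured at half
  prominence in frames.
* Missing frames (NaN) are excluded from every window; windows count
  non-missing frames.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .types import (
    DegenerateInputError,
    EpochDef,
    FluorescenceTrace,
    LarvaQuantError,
    NormalizedTrace,
    PeakSet,
    UndefinedRatioError,
)

__all__ = [
    "frames_to_seconds",
    "normalize_dff",
    "average_across_rois",
    "trapezoid_auc",
    "post_pre_ratio",
    "detect_peaks",
    "mean_peak_count",
    "response_onset",
    "response_duration",
    "amplitude_histogram",
]

#: Peak criteria for event counting (MinPeakProminence / MinPeakWidth).
DEFAULT_PEAK_PROMINENCE = 0.3
DEFAULT_PEAK_WIDTH = 10
#: Laxer prominence used only for locating the response onset.
DEFAULT_ONSET_PROMINENCE = 0.2
#: Pre/post stimulation AUC window, in frames.
DEFAULT_RATIO_WINDOW = 15
#: Pre-shock baseline window for the response-duration metric, in frames.
DEFAULT_BASELINE_FRAMES = 100


def frames_to_seconds(n: int, rate_hz: float) -> float:
    """Convert a frame count to seconds at the given acquisition rate.

    Examples: 600 frames at 5.2 Hz span 115.4 s; 15 frames at 2.6 Hz span
    5.8 s (values as conventionally reported to one decimal place; this
    function returns the unrounded quotient).
    """
    if rate_hz <= 0:
        raise LarvaQuantError(f"rate_hz must be > 0, got {rate_hz}")
    if n < 0:
        raise LarvaQuantError(f"frame count must be >= 0, got {n}")
    return n / rate_hz


def frames_to_seconds_reported(n: int, rate_hz: float) -> float:
    """`frames_to_seconds` rounded to one decimal, the reporting convention."""
    return round(frames_to_seconds(n, rate_hz), 1)


def normalize_dff(trace: FluorescenceTrace) -> NormalizedTrace:
    """Min-max normalize a fluorescence trace to dF/F in [0, 1].

    F_min and F_max are the extrema of the non-missing values over the whole
    recording; missing frames stay missing. A constant trace has no dynamic
    range and raises :class:`DegenerateInputError`.
    """
    values = trace.values
    good = ~np.isnan(values)
    if good.sum() < 2:
        raise DegenerateInputError("need at least 2 non-missing values")
    fmin = np.nanmin(values)
    fmax = np.nanmax(values)
    if fmax == fmin:
        raise DegenerateInputError("constant trace: F_max equals F_min")
    out = (values - fmin) / (fmax - fmin)
    return NormalizedTrace(roi_id=trace.roi_id, rate_hz=trace.rate_hz, values=out)


def average_across_rois(
    traces: list[NormalizedTrace],
) -> tuple[np.ndarray, np.ndarray]:
    """Framewise mean and SD across ROIs, skipping missing values.

    The SD band uses the population convention (ddof=0) so a single trace
    yields a zero-width band. Returns ``(mean, sd)`` arrays.
    """
    if len(traces) == 0:
        raise LarvaQuantError("need at least one trace")
    n = len(traces[0])
    rate = traces[0].rate_hz
    for t in traces[1:]:
        if len(t) != n:
            raise LarvaQuantError("traces have mismatched lengths")
        if t.rate_hz != rate:
            raise LarvaQuantError("traces have mismatched rates")
    stacked = np.vstack([t.values for t in traces])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=0)
    return mean, sd


def trapezoid_auc(trace, epoch: EpochDef) -> float:
    """Trapezoid-rule area under the trace within an epoch.

    The abscissa is the frame index; missing frames are excluded by joining
    the adjacent non-missing frames directly (the trapezoid spans the gap).
    Units are therefore value x frames.
    """
    values = np.asarray(trace.values, dtype=float)
    epoch.validate_for(len(values))
    window = values[epoch.start_frame : epoch.end_frame]
    frames = np.arange(epoch.start_frame, epoch.end_frame, dtype=float)
    good = ~np.isnan(window)
    if good.sum() < 2:
        raise DegenerateInputError("fewer than 2 non-missing frames in epoch")
    return float(np.trapezoid(window[good], frames[good]))


def post_pre_ratio(
    trace, stim_onset: int, window: int = DEFAULT_RATIO_WINDOW
) -> float:
    """Ratio of AUC after vs before a stimulus onset.

    F_post is the area under the curve over the first ``window`` non-missing
    frames at or after ``stim_onset``; F_pre over the last ``window``
    non-missing frames before it. Frames flagged missing (e.g. laser-switch
    gaps) are skipped, and the retained frames of each window are integrated
    on a uniform unit-spaced abscissa so both windows have identical support.
    """
    values = np.asarray(trace.values, dtype=float)
    if window < 2:
        raise LarvaQuantError(f"window must be >= 2 frames, got {window}")
    if not (0 <= stim_onset <= len(values)):
        raise LarvaQuantError(f"stim_onset {stim_onset} outside trace")
    pre_idx = np.flatnonzero(~np.isnan(values[:stim_onset]))
    post_idx = stim_onset + np.flatnonzero(~np.isnan(values[stim_onset:]))
    if len(pre_idx) < window or len(post_idx) < window:
        raise LarvaQuantError(
            f"need {window} non-missing frames on each side of the onset"
        )
    pre = values[pre_idx[-window:]]
    post = values[post_idx[:window]]
    f_pre = float(np.trapezoid(pre))
    f_post = float(np.trapezoid(post))
    if f_pre == 0:
        raise UndefinedRatioError("F_pre is 0; ratio undefined")
    return f_post / f_pre


def _leftmost_of_plateau(values: np.ndarray, idx: int) -> int:
    while idx > 0 and values[idx - 1] == values[idx]:
        idx -= 1
    return idx


def detect_peaks(
    trace: NormalizedTrace,
    min_prominence: float = DEFAULT_PEAK_PROMINENCE,
    min_width: float = DEFAULT_PEAK_WIDTH,
) -> PeakSet:
    """Detect calcium-event peaks on a normalized trace.

    A peak is a local maximum whose topographic prominence is at least
    ``min_prominence`` (dF/F fraction) and whose width at half prominence is
    at least ``min_width`` frames. Plateau ties resolve to the leftmost
    sample of the plateau. Missing frames are excluded; peak frames are
    reported in the original frame indexing.
    """
    values = np.asarray(trace.values, dtype=float)
    good_idx = np.flatnonzero(~np.isnan(values))
    if len(good_idx) <= min_width:
        raise LarvaQuantError("trace shorter than the minimum peak width")
    compact = values[good_idx]
    peaks, props = find_peaks(
        compact, prominence=min_prominence, width=min_width, rel_height=0.5
    )
    left_peaks = np.array(
        [_leftmost_of_plateau(compact, int(p)) for p in peaks], dtype=int
    )
    return PeakSet(
        frames=good_idx[left_peaks],
        prominences=props["prominences"],
        widths=props["widths"],
    )


def mean_peak_count(peak_sets: list[PeakSet]) -> float:
    """Mean peak count over the neurons of one larva."""
    if len(peak_sets) == 0:
        raise LarvaQuantError("larva group has no neurons")
    return float(np.mean([ps.count for ps in peak_sets]))


def response_onset(
    trace: NormalizedTrace,
    min_prominence: float = DEFAULT_ONSET_PROMINENCE,
    min_width: float = DEFAULT_PEAK_WIDTH,
) -> int | None:
    """Frame of the first activity increase, or None if activity never rises.

    Uses the same peak machinery as :func:`detect_peaks` but with a laxer
    prominence criterion (0.2), and returns the first qualifying peak frame.
    """
    peaks = detect_peaks(trace, min_prominence=min_prominence, min_width=min_width)
    if peaks.count == 0:
        return None
    return int(peaks.frames[0])


def response_duration(
    trace: NormalizedTrace,
    shock_frame: int,
    baseline_frames: int = DEFAULT_BASELINE_FRAMES,
) -> tuple[float, bool]:
    """Time for dF/F to return to the pre-shock baseline mean.

    The baseline is the mean dF/F over the ``baseline_frames`` frames
    immediately before ``shock_frame``. The duration runs until the first
    frame at or after the shock whose value is <= baseline. If the trace
    never returns, the duration is right-censored at the end of the
    recording and the second return value is True.
    """
    values = np.asarray(trace.values, dtype=float)
    if shock_frame < baseline_frames:
        raise LarvaQuantError(
            f"shock_frame {shock_frame} leaves no room for a "
            f"{baseline_frames}-frame baseline"
        )
    if shock_frame >= len(values):
        raise LarvaQuantError("shock_frame beyond the recording")
    base = values[shock_frame - baseline_frames : shock_frame]
    base = base[~np.isnan(base)]
    if len(base) == 0:
        raise DegenerateInputError("baseline window entirely missing")
    baseline = float(np.mean(base))
    # tolerance so a trace sitting exactly at the baseline value is not
    # pushed above it by summation rounding in the mean
    tol = 1e-12 * max(1.0, abs(baseline))
    tail = values[shock_frame:]
    below = np.flatnonzero(~np.isnan(tail) & (tail <= baseline + tol))
    if len(below) > 0:
        return float(below[0] / trace.rate_hz), False
    return float((len(values) - 1 - shock_frame) / trace.rate_hz), True


def amplitude_histogram(
    traces: list[NormalizedTrace],
    epoch: EpochDef,
    bin_width: float,
    mode: str = "frame",
    **peak_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of dF/F amplitudes within an epoch, pooled across traces.

    ``mode='frame'`` (default) pools every non-missing per-frame dF/F value
    in the epoch; ``mode='peak'`` pools the dF/F values at detected peak
    frames instead (peak criteria forwarded via ``peak_kwargs``). Bins
    partition [0, 1] with the given width; the final bin absorbs any
    remainder and its right edge is inclusive.

    Returns ``(counts, bin_edges)``.
    """
    if not (0 < bin_width <= 1):
        raise LarvaQuantError(f"bin_width must be in (0, 1], got {bin_width}")
    if mode not in ("frame", "peak"):
        raise LarvaQuantError(f"unknown mode {mode!r}")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    pooled = []
    for t in traces:
        epoch.validate_for(len(t))
        window = t.values[epoch.start_frame : epoch.end_frame]
        if mode == "frame":
            vals = window[~np.isnan(window)]
        else:
            peaks = detect_peaks(t, **peak_kwargs)
            sel = (peaks.frames >= epoch.start_frame) & (
                peaks.frames < epoch.end_frame
            )
            vals = t.values[peaks.frames[sel]]
        pooled.append(vals)
    pooled = np.concatenate(pooled) if pooled else np.empty(0)
    if pooled.size == 0:
        raise DegenerateInputError("no values in epoch")
    counts, _ = np.histogram(pooled, bins=edges)
    return counts, edges
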