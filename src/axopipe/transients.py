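"""Baseline correction to ΔF/F and significant-transient extraction.

Fluorescence baselines drift slowly (bleaching, slow z-drift), so the
baseline F0 is estimated per frame as a low percentile (default 8th) of
the fluorescence distribution in a sliding window (~20 s) centered on that
frame — long enough that sparse transients occupy a small fraction of each
window and do not lift the percentile, short enough to track bleaching.
The corrected trace is ΔF/F = (F − F0) / F0.

Significant transients are then peaks in ΔF/F that pass three gates
simultaneously: a minimum amplitude of 0.12 ΔF/F, a minimum duration of
0.5 s (width at half prominence) and a minimum prominence of 0.1 ΔF/F.
Everything outside the extent of a detected transient is forced to exactly
zero, producing the sparse, noise-free traces used for ROI grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io import SamplingInfo, TraceMatrix

__all__ = [
    "BaselineParams",
    "PeakParams",
    "Peak",
    "TransientSet",
    "rolling_percentile_baseline",
    "compute_dff",
    "detect_peaks",
    "mask_to_transients",
    "extract_transients",
]


@dataclass(frozen=True)
class BaselineParams:
    """Sliding-window length (s) and percentile for baseline estimation."""

    window_s: float = 20.0
    percentile: float = 8.0

    def __post_init__(self) -> None:
        if not self.window_s > 0:
            raise ValueError("window_s must be > 0")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


@dataclass(frozen=True)
class PeakParams:
    """Amplitude / duration / prominence gates for transient acceptance."""

    min_amplitude_dff: float = 0.12
    min_duration_s: float = 0.5
    min_prominence_dff: float = 0.1

    def __post_init__(self) -> None:
        if min(self.min_amplitude_dff, self.min_duration_s, self.min_prominence_dff) <= 0:
            raise ValueError("all peak gates must be strictly positive")


@dataclass
class Peak:
    """One detected transient peak with its extent (half-open frames)."""

    frame: int
    amplitude: float  # ΔF/F at the peak
    prominence: float
    width_s: float  # width at half prominence
    extent: tuple[int, int]


@dataclass
class TransientSet:
    """Per-ROI detected peaks plus the transient-masked ΔF/F matrix."""

    roi_ids: list[str]
    peaks: dict[str, list[Peak]]
    dff: TraceMatrix
    masked_dff: TraceMatrix
    baseline_params: BaselineParams = field(default_factory=BaselineParams)
    peak_params: PeakParams = field(default_factory=PeakParams)

    def n_peaks(self, roi_id: str | None = None) -> int:
        if roi_id is not None:
            return len(self.peaks[roi_id])
        return sum(len(p) for p in self.peaks.values())


def rolling_percentile_baseline(
    trace: np.ndarray, params: BaselineParams, sampling: SamplingInfo
) -> np.ndarray:
    """Per-frame percentile of a centered sliding window.

    The window spans ``window_s`` seconds (rounded to frames) and is
    truncated — not reflected — at the session edges, so no data is
    fabricated; ``baseline[t]`` is the ``percentile``-th percentile of
    ``trace[max(0, t-h) : t+h+1]`` with ``h = window_frames // 2``.
    """
    trace = np.asarray(trace, dtype=np.float64).ravel()
    n = trace.size
    win = sampling.seconds_to_frames(params.window_s)
    if win < 1 or win > n:
        raise ValueError(f"window of {win} frames invalid for trace of {n} frames")
    h = win // 2
    out = np.empty(n)
    full = 2 * h + 1
    if n >= full:
        # interior frames all share the same window length -> vectorized
        windows = np.lib.stride_tricks.sliding_window_view(trace, full)
        out[h : n - h] = np.percentile(windows, params.percentile, axis=1)
        edge = range(0, h)
        tail = range(n - h, n)
    else:
        edge, tail = range(0, n), range(0)
    for t in edge:
        out[t] = np.percentile(trace[: t + h + 1], params.percentile)
    for t in tail:
        out[t] = np.percentile(trace[max(0, t - h) :], params.percentile)
    return out


def compute_dff(trace: np.ndarray, baseline: np.ndarray, eps: float | None = None) -> np.ndarray:
    """ΔF/F from a trace and its per-frame baseline.

    ``dff[t] = (F[t] - F0[t]) / max(F0[t], eps)``. The divisor floor ``eps``
    (default: 1% of the trace's global median, never below 1e-6) guards
    against near-zero baselines in dim ROIs.
    """
    trace = np.asarray(trace, dtype=np.float64).ravel()
    baseline = np.asarray(baseline, dtype=np.float64).ravel()
    if trace.shape != baseline.shape:
        raise ValueError("trace and baseline must have the same length")
    if np.all(baseline <= 0):
        raise ValueError("baseline non-positive everywhere; cannot form ΔF/F")
    if eps is None:
        eps = max(0.01 * float(np.median(trace)), 1e-6)
    return (trace - baseline) / np.maximum(baseline, eps)


def detect_peaks(
    dff: np.ndarray, params: PeakParams, sampling: SamplingInfo
) -> list[Peak]:
    """Find ΔF/F peaks passing the amplitude, duration and prominence gates.

    Duration is width at half prominence; the gate is
    ``ceil(min_duration_s x frame_rate)`` frames. Each accepted peak is
    annotated with its extent: the prominence base interval, clipped on
    each side at the first frame where ΔF/F drops below 0 so that long
    shallow shoulders are not swept into the transient.
    """
    dff = np.asarray(dff, dtype=np.float64).ravel()
    if not np.isfinite(dff).all():
        raise ValueError("dff must be finite")
    min_width_frames = int(np.ceil(params.min_duration_s * sampling.frame_rate_hz))
    idx, props = find_peaks(
        dff,
        height=params.min_amplitude_dff,
        prominence=params.min_prominence_dff,
        width=min_width_frames,
        rel_height=0.5,
    )
    peaks = []
    for j, frame in enumerate(idx):
        left = int(props["left_bases"][j])
        right = int(props["right_bases"][j])
        # clip the extent where the trace crosses below zero
        below = np.flatnonzero(dff[left : frame + 1] < 0)
        if below.size:
            left = left + int(below[-1]) + 1
        below = np.flatnonzero(dff[frame:right + 1] < 0)
        if below.size:
            right = frame + int(below[0]) - 1
        peaks.append(
            Peak(
                frame=int(frame),
                amplitude=float(dff[frame]),
                prominence=float(props["prominences"][j]),
                width_s=float(props["widths"][j]) / sampling.frame_rate_hz,
                extent=(left, right + 1),
            )
        )
    return peaks


def mask_to_transients(dff: np.ndarray, peaks: list[Peak]) -> np.ndarray:
    """Zero every sample outside the union of peak extents."""
    dff = np.asarray(dff, dtype=np.float64).ravel()
    out = np.zeros_like(dff)
    for p in peaks:
        s, e = p.extent
        out[s:e] = dff[s:e]
    return out


def extract_transients(
    traces: TraceMatrix,
    baseline_params: BaselineParams | None = None,
    peak_params: PeakParams | None = None,
    subtract_only: bool = False,
) -> TransientSet:
    """Baseline-correct every ROI and extract its significant transients.

    ``subtract_only=True`` skips the division by F0 and works on the
    baseline-subtracted trace directly (same units as the input).
    """
    baseline_params = baseline_params or BaselineParams()
    peak_params = peak_params or PeakParams()
    dff_rows, masked_rows, peaks = [], [], {}
    for roi, row in zip(traces.roi_ids, traces.values):
        f0 = rolling_percentile_baseline(row, baseline_params, traces.sampling)
        dff = (row - f0) if subtract_only else compute_dff(row, f0)
        roi_peaks = detect_peaks(dff, peak_params, traces.sampling)
        dff_rows.append(dff)
        masked_rows.append(mask_to_transients(dff, roi_peaks))
        peaks[roi] = roi_peaks
    return TransientSet(
        roi_ids=list(traces.roi_ids),
        peaks=peaks,
        dff=traces.with_values(np.array(dff_rows)),
        masked_dff=traces.with_values(np.array(masked_rows)),
        baseline_params=baseline_params,
        peak_params=peak_params,
    )
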