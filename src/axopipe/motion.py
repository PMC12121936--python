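"""Detection and removal of z-plane movement artifacts.

When the brain shifts along the optical axis, a different slab of tissue is
sampled and many ROIs change their mean fluorescence at once — some up,
some down, but synchronously. Real calcium transients, by contrast, are
stereotyped in shape and asynchronous across ROIs. The population signature
of a z-shift is therefore a level change in the dominant mode of the
z-scored trace matrix.

The detection chain is:

1. z-score every ROI trace (population standard deviation) so ROIs are
   comparable regardless of brightness;
2. take the first principal component across ROIs, treating frames as
   observations — a single time series that concentrates the synchronous
   variance;
3. segment that series with bottom-up change-point detection: start from
   2-frame atoms and greedily merge the adjacent pair whose merge costs
   least under a squared-error segment cost, until the user-requested
   number of change points remains. The change-point count should be
   over-specified (default 4) and the classifier left to reject spurious
   segments;
4. classify segments as artifacts when their median level deviates from
   the baseline median by more than ``deviation_k`` robust scale units
   (1.4826 x MAD) AND the segment lasts at least
   ``min_artifact_duration_s`` — brief synchronous events are plausible
   population coactivity, while level shifts sustained for seconds are
   almost certainly z-motion.

The default ``deviation_k = 8`` is sized from the two competing regimes: a
z-shift moving >= 80% of N ROIs by >= 3 per-ROI standard deviations sets a
PC1 level of roughly ``3 sqrt(0.8 N)`` robust-scale units (>= 9 already at
N = 10, ~17 at N = 40), whereas a segment bracketing an ordinary calcium
transient — even a very large one carried by a single ROI — rarely exceeds
~6 units, because its PC1 excursion is bounded by the event z-score times
that ROI's loading and is further diluted by the segment median.

A static-fluorophore channel, when available, is pushed through the same
chain; artifact intervals that reappear there are confirmed as motion
(an activity-independent fluorophore cannot produce synchronous biology).
Flagged frames are then either dropped across all ROIs or used to split the
session into independently analyzable pieces.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .io import DegenerateSignalError, SamplingInfo, TraceMatrix

__all__ = [
    "SegmentationParams",
    "PCResult",
    "ArtifactIntervals",
    "IntervalSource",
    "MaskMode",
    "VerificationReport",
    "zscore_traces",
    "first_principal_component",
    "bottomup_segment",
    "classify_artifact_segments",
    "verify_with_static_channel",
    "apply_artifact_mask",
    "detect_artifacts",
]


class IntervalSource(str, enum.Enum):
    ACTIVITY = "activity_channel"
    STATIC = "static_channel"


class MaskMode(str, enum.Enum):
    DROP = "drop"
    SPLIT = "split"


@dataclass(frozen=True)
class SegmentationParams:
    """Change-point count, artifact-duration gate and level-deviation gate.

    ``n_change_points`` is deliberately a user input: over-specify it and
    let the duration/deviation classifier reject spurious segments.
    """

    n_change_points: int = 4
    min_artifact_duration_s: float = 2.0
    deviation_k: float = 8.0

    def __post_init__(self) -> None:
        if self.n_change_points < 1:
            raise ValueError("n_change_points must be >= 1")
        if not self.min_artifact_duration_s > 0:
            raise ValueError("min_artifact_duration_s must be > 0")
        if not self.deviation_k > 0:
            raise ValueError("deviation_k must be > 0")


@dataclass
class PCResult:
    """First principal component (a time series) and its variance share."""

    pc1: np.ndarray
    explained_variance_ratio: float


@dataclass
class ArtifactIntervals:
    """Sorted, non-overlapping half-open frame intervals flagged as z-shifts."""

    intervals: list[tuple[int, int]]
    source: IntervalSource = IntervalSource.ACTIVITY

    def __post_init__(self) -> None:
        for (s, e) in self.intervals:
            if not e > s:
                raise ValueError(f"interval ({s}, {e}) must satisfy end > start")
        for (_, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("intervals must be sorted and non-overlapping")

    def total_frames(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def mask(self, n_frames: int) -> np.ndarray:
        """Boolean frame mask, True inside flagged intervals."""
        m = np.zeros(n_frames, dtype=bool)
        for s, e in self.intervals:
            if e > n_frames or s < 0:
                raise ValueError(f"interval ({s}, {e}) outside [0, {n_frames})")
            m[s:e] = True
        return m


def zscore_traces(traces: TraceMatrix) -> TraceMatrix:
    """Standardize every ROI trace to mean 0, (population) sd 1."""
    mu = traces.values.mean(axis=1, keepdims=True)
    sd = traces.values.std(axis=1, keepdims=True)
    dead = np.flatnonzero(sd.ravel() == 0)
    if dead.size:
        raise DegenerateSignalError(
            f"zero-variance ROI(s): {[traces.roi_ids[i] for i in dead[:5]]}"
        )
    return traces.with_values((traces.values - mu) / sd)


def first_principal_component(zscored: TraceMatrix) -> PCResult:
    """Leading PCA mode of the ROI population, as a time series.

    Frames are treated as observations and ROIs as features, so ``pc1`` is
    the per-frame score on the leading eigenvector of the ROI covariance.
    Sign is fixed so the frame of maximum magnitude is positive.
    """
    X = zscored.values.T  # frames x ROIs
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    pc1 = U[:, 0] * S[0]
    total_var = float((S**2).sum())
    evr = float(S[0] ** 2 / total_var) if total_var > 0 else 0.0
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return PCResult(pc1=pc1, explained_variance_ratio=evr)


_ATOM = 2  # initial bottom-up segment width, frames


def bottomup_segment(series: np.ndarray, params: SegmentationParams) -> list[int]:
    """Bottom-up change-point detection under a squared-error cost.

    The series is cut into 2-frame atoms; the adjacent pair of segments
    whose merge increases the total within-segment sum of squared
    deviations least is merged repeatedly until exactly
    ``params.n_change_points`` interior breakpoints remain. Returns the
    sorted breakpoint frame indices.
    """
    series = np.asarray(series, dtype=np.float64).ravel()
    n = series.size
    if n < _ATOM * 4:
        raise ValueError(f"series length {n} too short for segmentation (need >= {_ATOM * 4})")
    n_segments_target = params.n_change_points + 1
    # atom boundaries; last atom absorbs any remainder
    starts = list(range(0, n - n % _ATOM, _ATOM))
    bounds = starts + [n]
    if len(starts) <= n_segments_target:
        raise ValueError(
            f"series of {n} frames yields only {len(starts)} atoms; cannot place "
            f"{params.n_change_points} change points"
        )

    csum = np.concatenate([[0.0], np.cumsum(series)])
    csum2 = np.concatenate([[0.0], np.cumsum(series**2)])

    def seg_cost(a: int, b: int) -> float:
        # sum of squared deviations from the segment mean over [a, b)
        s, s2, cnt = csum[b] - csum[a], csum2[b] - csum2[a], b - a
        return s2 - s * s / cnt

    # bounds[i] .. bounds[i+1] are the current segments
    costs = [seg_cost(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    merge_gain = [
        seg_cost(bounds[i], bounds[i + 2]) - costs[i] - costs[i + 1]
        for i in range(len(bounds) - 2)
    ]
    while len(bounds) - 1 > n_segments_target:
        i = int(np.argmin(merge_gain))
        costs[i] = seg_cost(bounds[i], bounds[i + 2])
        del bounds[i + 1], costs[i + 1], merge_gain[i]
        if i > 0:
            merge_gain[i - 1] = seg_cost(bounds[i - 1], bounds[i + 1]) - costs[i - 1] - costs[i]
        if i < len(merge_gain):
            merge_gain[i] = seg_cost(bounds[i], bounds[i + 2]) - costs[i] - costs[i + 1]
    return bounds[1:-1]


def _robust_scale(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def classify_artifact_segments(
    pc1: np.ndarray,
    breakpoints: list[int],
    params: SegmentationParams,
    sampling: SamplingInfo,
) -> ArtifactIntervals:
    """Flag segments whose level deviates from baseline for long enough.

    A segment is an artifact iff its median deviates from the baseline
    median by more than ``deviation_k`` robust scale units (1.4826 x MAD)
    AND it lasts at least ``min_artifact_duration_s``. The baseline is
    estimated in two passes: first over the whole series, then — after the
    first flagging round — over unflagged segments only, so that a large
    artifact does not drag the baseline toward itself. Adjacent flagged
    segments are merged.
    """
    pc1 = np.asarray(pc1, dtype=np.float64).ravel()
    n = pc1.size
    bounds = [0, *sorted(int(b) for b in breakpoints), n]
    if any(not 0 < b < n for b in breakpoints):
        raise ValueError("breakpoints must lie strictly inside the series")
    segs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    min_frames = params.min_artifact_duration_s * sampling.frame_rate_hz

    def flag_pass(baseline_med: float, scale: float) -> list[bool]:
        if scale == 0:
            scale = 1e-12
        return [
            abs(float(np.median(pc1[s:e])) - baseline_med) > params.deviation_k * scale
            and (e - s) >= min_frames
            for s, e in segs
        ]

    flags = flag_pass(float(np.median(pc1)), _robust_scale(pc1))
    unflagged = np.concatenate(
        [pc1[s:e] for (s, e), f in zip(segs, flags) if not f] or [pc1]
    )
    flags = flag_pass(float(np.median(unflagged)), _robust_scale(unflagged))

    intervals: list[tuple[int, int]] = []
    for (s, e), f in zip(segs, flags):
        if not f:
            continue
        if intervals and intervals[-1][1] == s:
            intervals[-1] = (intervals[-1][0], e)
        else:
            intervals.append((s, e))
    return ArtifactIntervals(intervals=intervals, source=IntervalSource.ACTIVITY)


def detect_artifacts(
    traces: TraceMatrix,
    params: SegmentationParams | None = None,
) -> tuple[ArtifactIntervals, PCResult]:
    """Full activity-channel chain: z-score -> PC1 -> segment -> classify."""
    params = params or SegmentationParams()
    pc = first_principal_component(zscore_traces(traces))
    bkps = bottomup_segment(pc.pc1, params)
    intervals = classify_artifact_segments(pc.pc1, bkps, params, traces.sampling)
    return intervals, pc


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


@dataclass
class VerificationReport:
    """Per-interval static-channel confirmation of flagged artifacts."""

    static_intervals: ArtifactIntervals
    overlaps: list[float] = field(default_factory=list)  # max Jaccard per activity interval
    confirmed: list[bool] = field(default_factory=list)

    @property
    def all_confirmed(self) -> bool:
        return all(self.confirmed) if self.confirmed else True


def verify_with_static_channel(
    static: TraceMatrix,
    intervals: ArtifactIntervals,
    params: SegmentationParams | None = None,
    overlap_threshold: float = 0.5,
) -> VerificationReport:
    """Cross-check activity-channel artifact intervals on the static channel.

    The static fluorophore carries no calcium signal, so a synchronous level
    shift that reappears there (Jaccard overlap >= ``overlap_threshold``
    with some static-channel interval) is confirmed as z-motion; an interval
    absent from the static channel is likely population coactivity and is
    reported unconfirmed.
    """
    params = params or SegmentationParams()
    if not intervals.intervals:
        return VerificationReport(
            static_intervals=ArtifactIntervals([], IntervalSource.STATIC)
        )
    static_found, _ = detect_artifacts(static, params)
    static_found = ArtifactIntervals(static_found.intervals, IntervalSource.STATIC)
    overlaps = [
        max((_jaccard(iv, siv) for siv in static_found.intervals), default=0.0)
        for iv in intervals.intervals
    ]
    return VerificationReport(
        static_intervals=static_found,
        overlaps=overlaps,
        confirmed=[o >= overlap_threshold for o in overlaps],
    )


def apply_artifact_mask(
    traces: TraceMatrix,
    intervals: ArtifactIntervals,
    mode: MaskMode = MaskMode.DROP,
) -> list[tuple[TraceMatrix, np.ndarray]]:
    """Remove flagged frames (``drop``) or split the session on them.

    Returns ``(matrix, frame_map)`` pairs, where ``frame_map[t]`` gives the
    original frame index of output frame ``t``. ``drop`` yields a single
    pair covering all unflagged frames; ``split`` yields one pair per
    contiguous unflagged stretch.
    """
    mode = MaskMode(mode)
    bad = intervals.mask(traces.n_frames)
    if bad.all():
        raise ValueError("artifact intervals cover every frame; nothing would remain")
    if mode == MaskMode.DROP:
        keep = np.flatnonzero(~bad)
        return [(traces.subset_frames(keep), keep)]
    pieces: list[tuple[TraceMatrix, np.ndarray]] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[True], bad, [True]]).astype(int)))
    # edges pair up as (start of good run, end of good run)
    for s, e in zip(edges[::2], edges[1::2]):
        frame_map = np.arange(s, e)
        pieces.append((traces.subset_frames(frame_map), frame_map))
    return pieces
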