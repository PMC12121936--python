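"""Core data containers and trace I/O.

The universal currency of the pipeline is a :class:`TraceMatrix`: one row of
raw fluorescence per ROI, sampled at a fixed frame rate. Traces arrive either
as plain CSV matrices or as a Suite2P output directory (from which only the
fluorescence arrays and the frame rate are consumed — x/y registration and
ROI detection happen upstream).

Conventions used throughout the package:

* frames are 0-based and every frame interval is half-open ``[start, end)``;
* ROI identifiers are opaque strings, preserved end-to-end;
* non-finite samples are a hard error at ingestion — an explicit repair
  helper (:func:`interpolate_nonfinite`) exists for users who want them
  linearly interpolated instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "SamplingInfo",
    "TraceMatrix",
    "FrequencyBand",
    "TraceFormatError",
    "TraceValidationError",
    "DegenerateSignalError",
    "read_trace_csv",
    "write_trace_csv",
    "read_suite2p_dir",
    "interpolate_nonfinite",
]


class TraceFormatError(ValueError):
    """Raised when an input file cannot be parsed as a trace matrix."""


class TraceValidationError(ValueError):
    """Raised when parsed data violates a trace invariant (e.g. NaN cells)."""


class DegenerateSignalError(ValueError):
    """Raised when a trace carries no usable signal (zero variance/power)."""


class Channel(str, enum.Enum):
    """Which fluorophore a trace matrix was recorded from."""

    ACTIVITY = "activity"  # calcium-dependent (e.g. GCaMP6s, green)
    STATIC = "static"  # activity-independent (e.g. mRuby, red)


@dataclass(frozen=True)
class SamplingInfo:
    """Acquisition geometry of a trace matrix.

    Parameters
    ----------
    frame_rate_hz
        Imaging frame rate in Hz. Resonant-scanner two-photon systems
        commonly run near 15.49 Hz, the default used by the simulator.
    n_frames, n_rois
        Matrix dimensions.
    """

    frame_rate_hz: float
    n_frames: int
    n_rois: int

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        # derived pieces (e.g. a 1-frame sliver after artifact splitting) may
        # be degenerate; the readers enforce >= 2 frames on actual inputs
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.n_rois < 1:
            raise ValueError(f"n_rois must be >= 1, got {self.n_rois}")

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate_hz / 2.0

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def seconds_to_frames(self, seconds: float) -> int:
        """Convert a duration to the nearest whole number of frames."""
        return int(round(seconds * self.frame_rate_hz))


@dataclass(frozen=True)
class FrequencyBand:
    """A frequency interval ``[low_hz, high_hz]`` inside (0, Nyquist)."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )

    def validate_for(self, sampling: SamplingInfo) -> None:
        if self.high_hz >= sampling.nyquist_hz:
            raise ValueError(
                f"band high edge {self.high_hz} Hz is not below the Nyquist "
                f"frequency {sampling.nyquist_hz:.4g} Hz"
            )


@dataclass
class TraceMatrix:
    """ROIs x frames fluorescence for one channel.

    ``values[i, t]`` is the fluorescence of ROI ``roi_ids[i]`` at frame ``t``,
    in arbitrary units. All values are finite by construction: the readers
    reject non-finite cells.
    """

    values: np.ndarray
    channel: Channel
    roi_ids: list[str]
    sampling: SamplingInfo = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise TraceValidationError(
                f"trace values must be 2-D (ROIs x frames), got {self.values.ndim}-D"
            )
        n_rois, n_frames = self.values.shape
        if (n_rois, n_frames) != (self.sampling.n_rois, self.sampling.n_frames):
            raise TraceValidationError(
                f"values shape {self.values.shape} inconsistent with sampling "
                f"({self.sampling.n_rois}, {self.sampling.n_frames})"
            )
        if len(self.roi_ids) != n_rois:
            raise TraceValidationError(
                f"{len(self.roi_ids)} roi_ids for {n_rois} trace rows"
            )
        self.roi_ids = [str(r) for r in self.roi_ids]
        _check_finite(self.values, self.roi_ids)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def frame_rate_hz(self) -> float:
        return self.sampling.frame_rate_hz

    def times_s(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.sampling.frame_rate_hz

    def with_values(self, values: np.ndarray, channel: Channel | None = None) -> "TraceMatrix":
        """New matrix with the same ROIs/sampling but different samples."""
        values = np.asarray(values, dtype=np.float64)
        sampling = self.sampling
        if values.shape[1] != self.n_frames:
            sampling = replace(self.sampling, n_frames=values.shape[1])
        return TraceMatrix(
            values=values,
            channel=channel or self.channel,
            roi_ids=list(self.roi_ids),
            sampling=sampling,
        )

    def subset_rois(self, indices: Sequence[int]) -> "TraceMatrix":
        indices = list(indices)
        return TraceMatrix(
            values=self.values[indices],
            channel=self.channel,
            roi_ids=[self.roi_ids[i] for i in indices],
            sampling=replace(self.sampling, n_rois=len(indices)),
        )

    def subset_frames(self, frame_index: np.ndarray) -> "TraceMatrix":
        frame_index = np.asarray(frame_index)
        return TraceMatrix(
            values=self.values[:, frame_index],
            channel=self.channel,
            roi_ids=list(self.roi_ids),
            sampling=replace(self.sampling, n_frames=int(frame_index.size)),
        )


def _check_finite(values: np.ndarray, roi_ids: Sequence[str]) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        i, t = np.argwhere(bad)[0]
        raise TraceValidationError(
            f"non-finite value at ROI {roi_ids[int(i)]!r} (row {int(i)}), "
            f"frame {int(t)}; use interpolate_nonfinite() to repair explicitly"
        )


def read_trace_csv(
    path: str | Path,
    frame_rate_hz: float,
    channel: Channel = Channel.ACTIVITY,
) -> TraceMatrix:
    """Read a trace matrix from CSV (one row per ROI).

    The first column is used as the ROI id when it is non-numeric; a fully
    numeric matrix gets synthesized ids ``"0" .. "n-1"``. Row order is
    preserved exactly.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=str)
    except pd.errors.ParserError as exc:
        raise TraceFormatError(f"{path}: ragged or malformed CSV ({exc})") from exc
    if df.empty:
        raise TraceFormatError(f"{path}: empty file")

    first_col = df.iloc[:, 0]
    first_numeric = pd.to_numeric(first_col, errors="coerce")
    has_id_column = first_numeric.isna().any() and not first_col.isna().any()
    if has_id_column:
        roi_ids = first_col.astype(str).tolist()
        numeric = df.iloc[:, 1:]
    else:
        roi_ids = [str(i) for i in range(len(df))]
        numeric = df

    if numeric.shape[1] < 2:
        raise TraceFormatError(f"{path}: need at least 2 frames per ROI")
    try:
        # Python float() per cell: exact round-trip of repr-printed values
        values = numeric.astype(np.float64).to_numpy()
    except (ValueError, TypeError):
        raw = numeric.to_numpy(dtype=object)
        coerced = numeric.apply(pd.to_numeric, errors="coerce").to_numpy()
        bad = np.isnan(coerced) & ~_is_nan_literal(raw)
        i, t = np.argwhere(bad)[0]
        raise TraceFormatError(
            f"{path}: non-numeric cell {raw[i, t]!r} at row {int(i)}, column {int(t)}"
        ) from None
    bad = ~np.isfinite(values)
    if bad.any():
        i, t = np.argwhere(bad)[0]
        raise TraceValidationError(
            f"{path}: non-finite value at row {int(i)} (ROI {roi_ids[int(i)]!r}), "
            f"frame {int(t)}"
        )

    sampling = SamplingInfo(frame_rate_hz, n_frames=values.shape[1], n_rois=values.shape[0])
    return TraceMatrix(values=values, channel=channel, roi_ids=roi_ids, sampling=sampling)


def _is_nan_literal(raw: np.ndarray) -> np.ndarray:
    out = np.zeros(raw.shape, dtype=bool)
    for idx, cell in np.ndenumerate(raw):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            out[idx] = True
        elif isinstance(cell, str) and cell.strip().lower() in {"nan", "inf", "-inf", "+inf"}:
            out[idx] = True
    return out


def write_trace_csv(traces: TraceMatrix, path: str | Path) -> None:
    """Write a trace matrix as CSV with the ROI id as the first column.

    Uses repr-precision floats so that ``read_trace_csv`` round-trips the
    values bit-identically.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for roi, row in zip(traces.roi_ids, traces.values):
            fh.write(roi + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_suite2p_dir(
    path: str | Path,
    channel: Channel = Channel.ACTIVITY,
    frame_rate_hz: float | None = None,
    respect_iscell: bool = False,
) -> TraceMatrix:
    """Read fluorescence traces from a Suite2P output directory.

    Loads ``F.npy`` (or ``F_chan2.npy`` for the static channel). By default
    *all* ROIs are returned — this pipeline performs its own ROI selection —
    but ``respect_iscell=True`` keeps only rows flagged in ``iscell.npy``.
    The frame rate is taken from ``ops.npy`` (key ``fs``) when present,
    otherwise ``frame_rate_hz`` is required.
    """
    path = Path(path)
    fname = "F.npy" if channel == Channel.ACTIVITY else "F_chan2.npy"
    fpath = path / fname
    if not fpath.exists():
        raise FileNotFoundError(f"missing fluorescence file {fpath}")
    values = np.load(fpath, allow_pickle=False)
    if values.ndim != 2:
        raise TraceValidationError(f"{fpath}: expected a 2-D ROIs x frames array")

    roi_ids = [str(i) for i in range(values.shape[0])]
    if respect_iscell:
        iscell_path = path / "iscell.npy"
        if not iscell_path.exists():
            raise FileNotFoundError(f"respect_iscell requested but {iscell_path} missing")
        iscell = np.load(iscell_path, allow_pickle=False)
        if iscell.shape[0] != values.shape[0]:
            raise TraceValidationError(
                f"iscell has {iscell.shape[0]} rows for {values.shape[0]} ROIs"
            )
        keep = iscell[:, 0].astype(bool) if iscell.ndim == 2 else iscell.astype(bool)
        values = values[keep]
        roi_ids = [r for r, k in zip(roi_ids, keep) if k]

    if frame_rate_hz is None:
        ops_path = path / "ops.npy"
        if ops_path.exists():
            ops = np.load(ops_path, allow_pickle=True).item()
            frame_rate_hz = float(ops.get("fs", 0)) or None
        if frame_rate_hz is None:
            raise ValueError(
                "frame rate not found in ops.npy; pass frame_rate_hz explicitly"
            )

    sampling = SamplingInfo(frame_rate_hz, n_frames=values.shape[1], n_rois=values.shape[0])
    return TraceMatrix(values=values, channel=channel, roi_ids=roi_ids, sampling=sampling)


def interpolate_nonfinite(values: np.ndarray) -> np.ndarray:
    """Repair non-finite samples by per-row linear interpolation.

    Explicit opt-in alternative to the readers' hard error. Leading/trailing
    gaps are filled with the nearest finite value. A fully non-finite row
    cannot be repaired and raises :class:`TraceValidationError`.
    """
    values = np.array(values, dtype=np.float64, copy=True)
    for i, row in enumerate(values):
        good = np.isfinite(row)
        if good.all():
            continue
        if not good.any():
            raise TraceValidationError(f"row {i} has no finite samples to interpolate from")
        x = np.arange(row.size)
        values[i] = np.interp(x, x[good], row[good])
    return values
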