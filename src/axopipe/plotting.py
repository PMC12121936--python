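"""Diagnostic plots for manual review of pipeline decisions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import TraceMatrix
from .motion import ArtifactIntervals, PCResult

__all__ = ["plot_artifact_overlay", "plot_pc1_segments"]


def plot_pc1_segments(
    pc: PCResult,
    intervals: ArtifactIntervals,
    frame_rate_hz: float,
    path: str | Path,
) -> None:
    """First principal component with flagged artifact periods shaded."""
    t = np.arange(pc.pc1.size) / frame_rate_hz
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(t, pc.pc1, lw=0.6, color="k")
    for s, e in intervals.intervals:
        ax.axvspan(s / frame_rate_hz, e / frame_rate_hz, color="red", alpha=0.3)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("PC1")
    ax.set_title(f"PC1 ({pc.explained_variance_ratio:.1%} of variance); "
                 f"{len(intervals.intervals)} flagged period(s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_artifact_overlay(
    traces: TraceMatrix,
    intervals: ArtifactIntervals,
    path: str | Path,
    max_rois: int = 12,
) -> None:
    """Per-ROI z-scored traces with flagged periods shaded, for eyeballing
    whether level shifts are synchronous across ROIs."""
    n = min(traces.n_rois, max_rois)
    t = traces.times_s()
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.2 * n), sharex=True, squeeze=False)
    for ax, roi, row in zip(axes.ravel(), traces.roi_ids[:n], traces.values[:n]):
        z = (row - row.mean()) / (row.std() or 1.0)
        ax.plot(t, z, lw=0.5, color="k")
        for s, e in intervals.intervals:
            ax.axvspan(s / traces.frame_rate_hz, e / traces.frame_rate_hz,
                       color="red", alpha=0.3)
        ax.set_ylabel(roi, rotation=0, ha="right", fontsize=7)
        ax.set_yticks([])
    axes.ravel()[-1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
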