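"""Find and remove z-plane movement artifacts.

A z-shift changes the fluorescence level of most ROIs at once (in random
directions). The detector z-scores the selected ROIs, takes the first
principal component, segments it bottom-up, flags segments whose level
deviates from baseline for >= 2 s, verifies them on the static channel,
and drops the flagged frames.
"""

import numpy as np

from axopipe import (
    MaskMode,
    SimConfig,
    ZShiftSpec,
    apply_artifact_mask,
    detect_artifacts,
    select_rois,
    simulate_session,
    smooth_traces,
    verify_with_static_channel,
)

session = simulate_session(
    SimConfig(n_rois=300, n_frames=3100, fraction_noise_rois=0.87, seed=3,
              z_shifts=(ZShiftSpec(90, 10, 3.0, 0.8),))
)
smoothed = smooth_traces(session.activity)
keep = list(np.flatnonzero(select_rois(smoothed).selected))
selected = smoothed.subset_rois(keep)

intervals, pc = detect_artifacts(selected)
fs = selected.frame_rate_hz
print(f"PC1 captures {pc.explained_variance_ratio:.0%} of population variance")
for s, e in intervals.intervals:
    print(f"flagged artifact: frames [{s}, {e})  =  {s/fs:.1f}-{e/fs:.1f} s")
print(f"planted truth:    frames {session.truth.artifact_intervals}")

report = verify_with_static_channel(session.static.subset_rois(keep), intervals)
print(f"static-channel confirmation: {report.confirmed} "
      f"(Jaccard overlap {[round(o, 2) for o in report.overlaps]})")

(cleaned, frame_map), = apply_artifact_mask(selected, intervals, MaskMode.DROP)
print(f"dropped {selected.n_frames - cleaned.n_frames} frames; "
      f"{cleaned.n_frames} clean frames remain")
# A confirmed interval means the same synchronous level change appears in
# the activity-independent fluorophore - it is motion, not biology.
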