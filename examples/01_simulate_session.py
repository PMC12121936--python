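"""Generate a synthetic two-channel imaging session with planted truth.

Builds a 200-second session of 100 ROIs (90% noise-only, as typical for
subcellular segmentation output) with one planted z-shift and two
same-axon groups, then prints what the generator planted. The companion
truth object is what the rest of the examples test the pipeline against.
"""

from axopipe import SimConfig, ZShiftSpec, simulate_session

config = SimConfig(
    n_rois=100,
    n_frames=3100,  # ~200 s at 15.49 Hz
    fraction_noise_rois=0.8,
    groups=(4, 4),
    z_shifts=(ZShiftSpec(start_s=90, duration_s=10, magnitude_sd=3.0, affected_fraction=0.8),),
    seed=0,
)
session = simulate_session(config)

truth = session.truth
print(f"activity matrix: {session.activity.n_rois} ROIs x {session.activity.n_frames} frames")
print(f"active ROIs (carry transients): {int(truth.active.sum())}")
print(f"noise-only ROIs:                {int((~truth.active).sum())}")
print(f"same-axon groups: {[len(g) for g in truth.groups]} members each")
print(f"planted z-shift frames: {truth.artifact_intervals}")
n_events = sum(len(v) for v in truth.event_times_s.values())
print(f"total planted transient events: {n_events}")
# The static channel carries the same z-shift but no calcium events; it is
# the control used later to confirm that flagged periods are motion.
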