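"""Select transient-carrying ROIs by normalized band power.

Smooths the traces, measures the fraction of each ROI's spectral power in
the 0.03-0.13 Hz transient band, and keeps ROIs above the 0.3 threshold.
Prints the confusion against the generator's planted active/noise labels:
a good run recovers nearly all active ROIs and discards nearly all noise.
"""

import numpy as np

from axopipe import SimConfig, select_rois, simulate_session, smooth_traces

session = simulate_session(SimConfig(n_rois=200, seed=1))
smoothed = smooth_traces(session.activity)
result = select_rois(smoothed)

active = session.truth.active
tp = int((result.selected & active).sum())
fp = int((result.selected & ~active).sum())
print(f"band {result.params.band.low_hz}-{result.params.band.high_hz} Hz, "
      f"threshold {result.params.power_threshold}")
print(f"selected {result.n_selected}/{session.activity.n_rois} ROIs "
      f"({tp} planted-active, {fp} noise)")
print(f"sensitivity: {tp / active.sum():.2f}   "
      f"specificity: {int((~result.selected & ~active).sum()) / (~active).sum():.2f}")
print("example powers: active",
      np.round(result.normalized_power[active][:4], 3),
      "| noise", np.round(result.normalized_power[~active][:4], 3))
# Active ROIs concentrate power in the slow transient band (values well
# above 0.3); noise ROIs spread power broadly and score near zero.
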