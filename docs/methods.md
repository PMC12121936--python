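# Methods

This note records the models behind each pipeline stage, the parameters
that matter, the numerical choices where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate about real
recordings.

## Signal model

A subcellular ROI's fluorescence is modeled as

    F(t) = F0 · (1 + s(t)) · b(t) + F0 · σ · ε(t)

with `s(t)` the calcium signal in ΔF/F units (zero for noise-only ROIs),
`b(t) = exp(−t/τ_bleach)` a multiplicative bleaching drift, and `ε` white
shot-like noise. A transient is the double-exponential indicator response
`k(t) = (1 − e^(−t/τ_rise)) e^(−t/τ_decay)`, normalized to unit peak;
`s(t)` is a Poisson event train convolved with `k`. For a GCaMP6s-like
indicator (τ_rise ≈ 0.2 s, τ_decay ≈ 1.5 s) the kernel's power lies
almost entirely below 0.5 Hz, which is what makes frequency-domain ROI
selection work at a ~15 Hz frame rate.

## Smoothing

Savitzky–Golay, window 15 frames (~1 s at 15.49 Hz), polynomial order 3.
The filter reproduces polynomials up to the chosen order exactly, so the
transient rise is preserved while frame noise is suppressed. The window
length shifts the apparent transient band: heavier smoothing depresses
high-frequency content and inflates the in-band fraction for all ROIs, so
smoothing and band threshold should be treated as a pair. Both are
exposed (`smoothing.window_frames`, `smoothing.polyorder`); edge frames
use polynomial fits on truncated windows so the trace length is
unchanged.

## Band-power ROI selection

The selection statistic is spectral: the periodogram of the
mean-subtracted smoothed trace, with the in-band sum divided by the total
over all positive-frequency bins. Dividing within the *same* unfiltered
spectrum makes the ratio exactly bounded by 1; the DC bin is excluded so
slow offsets cannot dominate the denominator. Band membership is by bin
center. The zero-phase Butterworth bandpass (low-pass at the upper edge,
then high-pass at the lower edge, each applied forward and backward) is
used for trace conditioning and timing checks, not for the statistic
itself.

Default band 0.03–0.13 Hz; threshold 0.3, strict inequality (a power
exactly at threshold is discarded), so raising the threshold can only
shrink the selection. Automatic band estimation compares the mean
exemplar spectrum against the mean population spectrum and returns the
longest run (≥ 3 bins) where the exemplar exceeds 1.5× the population,
ties broken toward lower frequency; it exists because the correct band
depends on indicator kinetics and structure imaged, and should be
re-derived per dataset.

Plain periodograms (no Welch averaging) are used deliberately: selection
integrates power over a band, which is robust to single-bin variance, and
the unaveraged spectrum keeps the statistic exactly 1-bounded and
length-independent after normalization.

## z-shift detection

Frames are observations, ROIs are features; every ROI is z-scored with
the population standard deviation (the choice of population vs sample sd
cancels in everything downstream). The first principal component is a
time series concentrating synchronous variance; its sign is fixed so the
frame of maximum magnitude is positive.

Bottom-up segmentation starts from 2-frame atoms and greedily merges the
adjacent pair with the smallest increase in within-segment sum of squared
deviations until the requested number of interior change points remains
(default 4). The count is a user input by design: over-specify and let
the classifier reject. Runtime is O(n²) in atoms via a vectorized
merge-cost scan, well under a second for typical sessions.

A segment is classified as artifact iff

* |median(segment) − median(baseline)| > `deviation_k` × robust scale, and
* the segment lasts ≥ `min_artifact_duration_s` (default 2 s — genuine
  population coactivity rarely sustains beyond a second or two).

The baseline median and robust scale (1.4826 × MAD) are estimated in two
passes, the second over unflagged segments only, so a large artifact does
not drag the baseline toward itself. `deviation_k` defaults to 8, sized
between the two regimes it must separate: a z-shift moving ≥ 80% of N
ROIs by ≥ 3 per-ROI sd sets a PC1 level of roughly 3·√(0.8·N)
robust-scale units (≥ 9 at N = 10, ~17 at N = 40), while a segment
bracketing even a very large single-ROI transient rarely exceeds ~6 units
(its PC1 excursion is bounded by the event z-score times that ROI's
loading, then diluted by the segment median). A lower k (3–5) flags
ordinary transient bursts on a third or more of artifact-free sessions.

Verification with a static fluorophore runs the identical chain on the
second channel and confirms an interval when its Jaccard overlap with
some static-channel interval is ≥ 0.5. In the full pipeline, only
*confirmed* intervals are removed when a static channel is available:
an unconfirmed synchronous period is most likely biology. Removal either
drops the flagged frames across all ROIs or splits the session into
independently analyzable pieces with frame maps back to the original
indices (frames are 0-based, intervals half-open).

Detection runs on the *selected* ROIs (the pipeline's stage order): on
the full ROI set, the shared bleaching drift of the ~90% noise ROIs
dominates PC1 and masks shifts.

**Known limitations.** (i) With few transient-carrying ROIs (≈10), a
3-sd shift's PC1 level (~9 units) sits near the threshold and recovery
degrades; population-PCA detection wants a few tens of active ROIs.
(ii) A shift large enough to push noise-only ROIs over the band-power
threshold lets shift-dominated noise ROIs into the selection; their
coherent bleaching drift inflates PC1's robust scale and can mask shorter
(~8 s) shifts at some session positions. The PC1 diagnostic plot and the
static channel are the remedies; 10-s shifts were recovered at every
position tested. (iii) Within-frame/nonrigid motion and rhythmic
(breathing, heartbeat) artifacts are out of scope.

## Baseline correction and transient extraction

F₀ is the per-frame 8th percentile of a centered ~20 s window, truncated
(not reflected) at the session edges — reflection would fabricate data.
The percentile window is long relative to transient duty cycle, so sparse
events do not lift it, and short relative to bleaching, so drift is
tracked. ΔF/F divides by `max(F0, ε)` with ε = 1% of the trace's global
median (floor 1e-6), guarding dim ROIs; a `subtract_only` mode skips the
division for users who want baseline-subtracted raw units.

Peaks must pass all three gates simultaneously: amplitude ≥ 0.12 ΔF/F,
width at half prominence ≥ 0.5 s (duration is interpreted as the standard
half-prominence width), prominence ≥ 0.1 ΔF/F. The amplitude gate is
absolute post-correction ΔF/F height. A transient's extent is its
prominence base interval, clipped on each side at the first frame where
ΔF/F crosses below zero, so long shallow shoulders are not swept in;
outside the union of extents the masked trace is exactly zero.

## Grouping

Correlations are computed on transient-masked ΔF/F (clustering follows
peak detection in the pipeline; a flag allows raw ΔF/F). Zero-lag Pearson
correlation implements "zero-phase cross-correlation"; no lag search is
performed because group members respond to the same spikes under the same
indicator kinetics. All-zero masked traces (no detected transients) are
reported as forced singletons rather than entering the matrix.

The prefilter (max off-diagonal r > 0.8) removes ROIs that cannot belong
to a multi-ROI group; candidates are clustered by agglomerative linkage
(average, on 1 − r; configurable) and by k-means on correlation-profile
rows with 10 seeded restarts. Both are scored with the same 1 − r
silhouette so the methods are comparable; k scans 2 … ⌊n/2⌋ and the
silhouette-optimal k wins. A maximum silhouette below 0.25 triggers an
explicit warning that the correlation structure does not support
grouping.

Ground truth from paired environments: an edge joins two ROIs when their
correlation exceeds 0.7 in *both* environments; groups are connected
components. Transitive closure is the only partition-consistent reading
of pairwise consistency and is applied knowingly: a chain i–j–k is one
group even if r(i,k) falls short. AMI between a clustering and the truth
is computed over candidates plus singletons, each singleton its own group
in both partitions.

## Synthetic sessions: what they show and what they do not

Generator defaults describe a realistic axon-GCaMP6s recording: 15.49 Hz,
6000 frames (~6.5 min), 90% noise-only ROIs, event rate 0.03 Hz, kernel
τ = 0.2/1.5 s, log-normal event amplitudes (mean 1.0, sd 0.5 ΔF/F —
bouton transients are large), shot noise 0.03 ΔF/F per frame, bleaching
τ = 1800 s, baseline F₀ uniform in 100–300 au (static channel at half
brightness). z-shifts add a constant step over the interval to both
channels with per-ROI random sign and magnitude uniform in 0.5–1.5× the
stated size (in units of that ROI's temporal sd). Group members share one
event train scaled by a per-member gain in 0.5–1.5.

Motion tests use sessions of 300 ROIs at 87% noise (~40 selected ROIs
entering detection, a typical FOV after selection) and 3100 frames;
clustering tests use 4-ROI groups over 3000 frames in paired
environments. These sizes keep the full suite and the acceptance script
to a few minutes; all stage behavior is size-stable above them.

Passing tests demonstrate internal correctness (oracle agreement, gate
exactness, determinism) and recovery under the stated statistical model.
They do not capture: correlated noise between ROIs sharing neuropil,
non-Poisson (behaviorally structured) event trains, nonstationary noise,
slow z-drift (as opposed to abrupt shifts), or segmentation errors
upstream. The selection threshold, frequency band, and artifact
parameters should be re-examined on each real dataset; every number
quoted here is a config default, not a constant.

## Reproducibility

Every stochastic component (generator, k-means restarts) is seeded; the
pipeline manifest contains a hash of the scientific configuration and no
timestamps, so identical configuration + seed ⇒ byte-identical outputs.
The acceptance script derives all of its seeds from a single `--seed`.
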