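import numpy as np
import pytest

from axopipe import (
    BaselineParams,
    PeakParams,
    SamplingInfo,
    compute_dff,
    detect_peaks,
    extract_transients,
    mask_to_transients,
    rolling_percentile_baseline,
    simulate_session,
    smooth_traces,
    transient_kernel,
)
from axopipe.simulate import SimConfig

from conftest import FS, make_traces

SAMP = SamplingInfo(FS, 2000, 1)


def brute_force_baseline(trace, window_s=20.0, percentile=8.0, fs=FS):
    win = int(round(window_s * fs))
    h = win // 2
    n = len(trace)
    return np.array(
        [np.percentile(trace[max(0, t - h) : min(n, t + h + 1)], percentile)
         for t in range(n)]
    )


class TestBaseline:
    def test_constant_trace(self):
        b = rolling_percentile_baseline(np.full(2000, 4.2), BaselineParams(), SAMP)
        np.testing.assert_allclose(b, 4.2)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_match_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = 100 + 10 * rng.standard_normal(2000)
        got = rolling_percentile_baseline(x, BaselineParams(), SAMP)
        np.testing.assert_array_equal(got, brute_force_baseline(x))

    def test_sparse_transients_do_not_lift_baseline(self):
        x = np.full(2000, 50.0)
        k = transient_kernel(0.2, 1.5, SAMP)
        for pos in (300, 900, 1500):  # <8% duty cycle in every 20 s window
            x[pos : pos + k.size] += 30 * k
        b = rolling_percentile_baseline(x, BaselineParams(), SAMP)
        np.testing.assert_allclose(b, 50.0, atol=0.5)

    def test_linear_drift_tracked(self):
        x = 100 + 0.05 * np.arange(2000)
        b = rolling_percentile_baseline(x, BaselineParams(), SAMP)
        lag = BaselineParams().window_s * 0.05 * FS  # one window's worth of slope
        assert np.max(np.abs(b - x)) <= lag

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            rolling_percentile_baseline(
                np.zeros(100), BaselineParams(), SamplingInfo(FS, 100, 1)
            )


class TestDff:
    def test_identity_baseline_gives_zero(self):
        x = np.linspace(100, 120, 500)
        np.testing.assert_allclose(compute_dff(x, x), 0.0)

    def test_doubled_trace_gives_one(self):
        f0 = np.full(500, 80.0)
        np.testing.assert_allclose(compute_dff(2 * f0, f0), 1.0)

    def test_planted_amplitude_recovered(self):
        session = simulate_session(
            SimConfig(n_rois=6, n_frames=3000, fraction_noise_rois=0.0,
                      noise_sd=0.001, bleach_tau_s=1e9, event_rate_hz=0.01, seed=4)
        )
        tset = extract_transients(session.activity)
        for roi in session.truth.roi_ids:
            amps = np.array(session.truth.event_amplitudes[roi])
            times = np.array(session.truth.event_times_s[roi])
            for p in tset.peaks[roi]:
                t = p.frame / FS
                near = np.abs(times - (t - 0.45)) < 1.0  # onset ~0.45 s before peak
                if near.sum() == 1:  # isolated event
                    assert p.amplitude == pytest.approx(amps[near][0], rel=0.05)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            compute_dff(np.ones(10), -np.ones(10))


class TestDetectPeaks:
    def _transient(self, amplitude, width_frames=31, n=2000, pos=1000):
        x = np.zeros(n)
        t = np.arange(width_frames) - width_frames // 2
        x[pos - width_frames // 2 : pos + width_frames // 2 + 1] = (
            amplitude * np.exp(-0.5 * (t / (width_frames / 6)) ** 2)
        )
        return x

    def test_clear_transient_detected_once(self):
        peaks = detect_peaks(self._transient(0.5), PeakParams(), SAMP)
        assert len(peaks) == 1
        assert peaks[0].frame == 1000
        assert peaks[0].amplitude == pytest.approx(0.5, abs=1e-9)

    def test_subthreshold_amplitude_rejected(self):
        assert detect_peaks(self._transient(0.11), PeakParams(), SAMP) == []

    def test_single_frame_spike_fails_duration_gate(self):
        x = np.zeros(2000)
        x[1000] = 1.0
        assert detect_peaks(x, PeakParams(), SAMP) == []

    def test_gate_exactness_on_random_traces(self):
        rng = np.random.default_rng(0)
        params = PeakParams()
        min_w = np.ceil(params.min_duration_s * FS) / FS
        samp = SamplingInfo(FS, 400, 1)
        for _ in range(200):
            x = rng.standard_normal(400) * 0.08
            x = np.convolve(x, np.ones(5) / 5, mode="same")
            for p in detect_peaks(x, params, samp):
                assert p.amplitude >= params.min_amplitude_dff
                assert p.prominence >= params.min_prominence_dff
                assert p.width_s >= min_w - 1e-12


class TestMasking:
    def test_no_peaks_all_zero(self):
        x = np.random.default_rng(0).standard_normal(100)
        np.testing.assert_array_equal(mask_to_transients(x, []), 0.0)

    def test_values_kept_inside_extent_only(self):
        x = np.arange(100.0)
        from axopipe.transients import Peak

        p = Peak(frame=60, amplitude=1.0, prominence=1.0, width_s=1.0, extent=(50, 90))
        out = mask_to_transients(x, [p])
        np.testing.assert_array_equal(out[50:90], x[50:90])
        assert (out[:50] == 0).all() and (out[90:] == 0).all()

    def test_overlapping_extents_union(self):
        from axopipe.transients import Peak

        x = np.ones(100)
        ps = [Peak(30, 1, 1, 1, (20, 50)), Peak(45, 1, 1, 1, (40, 70))]
        out = mask_to_transients(x, ps)
        assert (out[20:70] == 1).all()
        assert (out[:20] == 0).all() and (out[70:] == 0).all()


def test_detection_power_and_false_peak_rate():
    """>=90% of planted events recovered within 0.5 s; false peaks on
    smoothed pure-noise traces are rare (<0.1/min)."""
    kernel_lag_s = 0.45  # double-exponential kernel peak latency
    hits = total = 0
    for seed in range(3):
        session = simulate_session(
            SimConfig(n_rois=10, n_frames=3000, fraction_noise_rois=0.0, seed=seed)
        )
        tset = extract_transients(smooth_traces(session.activity))
        for roi in session.truth.roi_ids:
            times = np.array(session.truth.event_times_s[roi])
            amps = np.array(session.truth.event_amplitudes[roi])
            times = times[amps >= 0.3]
            det = np.array([p.frame for p in tset.peaks[roi]]) / FS
            total += times.size
            hits += sum(
                1 for t in times
                if det.size and np.min(np.abs(det - (t + kernel_lag_s))) <= 0.5
            )
    assert total > 50
    assert hits / total >= 0.9

    false_peaks = minutes = 0
    rng = np.random.default_rng(99)
    samp = SamplingInfo(FS, 4000, 1)
    for _ in range(10):
        x = 200.0 * (1 + 0.03 * rng.standard_normal(4000))
        sm = smooth_traces(make_traces(x)).values[0]
        b = rolling_percentile_baseline(sm, BaselineParams(), samp)
        false_peaks += len(detect_peaks(compute_dff(sm, b), PeakParams(), samp))
        minutes += 4000 / FS / 60
    assert false_peaks / minutes <= 0.1
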