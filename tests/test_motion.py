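import numpy as np
import pytest

from axopipe import (
    ArtifactIntervals,
    MaskMode,
    SamplingInfo,
    SegmentationParams,
    apply_artifact_mask,
    bottomup_segment,
    classify_artifact_segments,
    detect_artifacts,
    first_principal_component,
    verify_with_static_channel,
    zscore_traces,
)
from axopipe.io import DegenerateSignalError
from axopipe.motion import IntervalSource

from conftest import FS, make_traces

SAMP = SamplingInfo(FS, 3000, 1)


class TestZscore:
    def test_closed_form(self):
        z = zscore_traces(make_traces([1.0, 2.0, 3.0])).values[0]
        np.testing.assert_allclose(z, [-1.22474487, 0.0, 1.22474487])

    def test_constant_row_rejected_by_name(self):
        tm = make_traces(np.vstack([np.arange(10.0), np.full(10, 2.0)]),
                         roi_ids=["ok", "dead"])
        with pytest.raises(DegenerateSignalError, match="dead"):
            zscore_traces(tm)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        z1 = zscore_traces(make_traces(x)).values[0]
        z2 = zscore_traces(make_traces(5.0 * x + 7.0)).values[0]
        np.testing.assert_allclose(z1, z2, atol=1e-12)


class TestFirstPC:
    def test_identical_rows_rank_one(self):
        x = np.sin(np.linspace(0, 20, 500))
        pc = first_principal_component(make_traces(np.vstack([x, x])))
        assert pc.explained_variance_ratio == pytest.approx(1.0)
        c = np.corrcoef(pc.pc1, x)[0, 1]
        assert abs(c) > 0.999999

    def test_anticorrelated_rows_rank_one(self):
        x = np.sin(np.linspace(0, 20, 500))
        pc = first_principal_component(make_traces(np.vstack([x, -x])))
        assert pc.explained_variance_ratio == pytest.approx(1.0)

    def test_shared_step_appears_as_level_shift(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 3000))
        X[:, 1000:1160] += 4.0 * rng.choice([-1.0, 1.0], size=(60, 1))
        pc = first_principal_component(zscore_traces(make_traces(X)))
        inside = np.median(pc.pc1[1000:1160])
        outside = np.median(np.delete(pc.pc1, slice(1000, 1160)))
        mad = 1.4826 * np.median(np.abs(pc.pc1 - np.median(pc.pc1)))
        assert abs(inside - outside) > 8 * mad


class TestBottomUp:
    def exhaustive_scan(self, x, n_bkps):
        n = len(x)
        cs = np.concatenate([[0], np.cumsum(x)])
        cs2 = np.concatenate([[0], np.cumsum(np.asarray(x) ** 2)])

        def cost(a, b):
            s, s2 = cs[b] - cs[a], cs2[b] - cs2[a]
            return s2 - s * s / (b - a)

        if n_bkps == 1:
            cands = [(cost(0, b) + cost(b, n), (b,)) for b in range(2, n - 1)]
        else:
            cands = [
                (cost(0, b1) + cost(b1, b2) + cost(b2, n), (b1, b2))
                for b1 in range(2, n - 3)
                for b2 in range(b1 + 2, n - 1)
            ]
        return min(cands)[1]

    @pytest.mark.parametrize("seed", range(5))
    def test_single_step_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([np.zeros(100), 5.0 * np.ones(200)])
        x += 0.5 * rng.standard_normal(300)
        got = bottomup_segment(x, SegmentationParams(n_change_points=1))
        (want,) = self.exhaustive_scan(x, 1)
        assert abs(got[0] - want) <= 2

    @pytest.mark.parametrize("seed", range(3))
    def test_two_steps_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([np.zeros(100), 5.0 * np.ones(100), np.zeros(100)])
        x += 0.5 * rng.standard_normal(300)
        got = bottomup_segment(x, SegmentationParams(n_change_points=2))
        want = self.exhaustive_scan(x, 2)
        assert all(abs(g - w) <= 2 for g, w in zip(got, want))

    def test_breakpoint_count_contract_on_noise(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(3000)
        bkps = bottomup_segment(x, SegmentationParams(n_change_points=4))
        assert len(bkps) == 4
        assert bkps == sorted(bkps)
        iv = classify_artifact_segments(x, bkps, SegmentationParams(), SAMP)
        assert iv.intervals == []

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            bottomup_segment(np.zeros(5), SegmentationParams())


class TestClassify:
    def test_planted_level_shift_flagged_exactly(self):
        rng = np.random.default_rng(0)
        pc1 = rng.standard_normal(3000)
        mad = 1.4826 * np.median(np.abs(pc1 - np.median(pc1)))
        pc1[1000:1155] += 12 * mad  # ~10 s at 15.49 Hz
        iv = classify_artifact_segments(
            pc1, [700, 1000, 1155, 2200], SegmentationParams(), SAMP
        )
        assert iv.intervals == [(1000, 1155)]

    def test_flat_series_nothing_flagged(self):
        iv = classify_artifact_segments(
            np.zeros(3000), [500, 1500], SegmentationParams(), SAMP
        )
        assert iv.intervals == []

    def test_short_elevation_rejected_by_duration_gate(self):
        rng = np.random.default_rng(1)
        pc1 = rng.standard_normal(3000)
        pc1[1000:1007] += 50.0  # huge but only ~0.45 s
        iv = classify_artifact_segments(
            pc1, [1000, 1007], SegmentationParams(), SAMP
        )
        assert iv.intervals == []


class TestVerification:
    def test_shared_shift_confirmed(self):
        rng = np.random.default_rng(4)
        step = 6.0 * rng.choice([-1.0, 1.0], size=(40, 1))
        act = rng.standard_normal((40, 3000))
        red = rng.standard_normal((40, 3000))
        act[:, 1200:1360] += step
        red[:, 1200:1360] += step
        intervals, _ = detect_artifacts(make_traces(act))
        assert intervals.intervals, "activity-channel shift not detected"
        report = verify_with_static_channel(make_traces(red), intervals)
        assert all(report.confirmed)
        assert min(report.overlaps) >= 0.8

    def test_coactivity_without_static_signature_unconfirmed(self):
        rng = np.random.default_rng(5)
        act = rng.standard_normal((40, 3000))
        act[:, 1200:1360] += 6.0  # synchronous same-sign "activity"
        red = rng.standard_normal((40, 3000))  # static channel stays flat
        intervals, _ = detect_artifacts(make_traces(act))
        assert intervals.intervals
        report = verify_with_static_channel(make_traces(red), intervals)
        assert not any(report.confirmed)

    def test_empty_intervals_empty_report(self):
        rng = np.random.default_rng(6)
        report = verify_with_static_channel(
            make_traces(rng.standard_normal((5, 3000))),
            ArtifactIntervals([], IntervalSource.ACTIVITY),
        )
        assert report.confirmed == [] and report.overlaps == []


class TestApplyMask:
    def _traces(self):
        return make_traces(np.arange(3000.0)[None, :].repeat(2, axis=0))

    def test_drop_arithmetic(self):
        out = apply_artifact_mask(
            self._traces(), ArtifactIntervals([(100, 200)]), MaskMode.DROP
        )
        assert len(out) == 1
        piece, fmap = out[0]
        assert piece.n_frames == 2900
        assert 150 not in fmap and fmap[100] == 200

    def test_split_pieces_and_frame_maps(self):
        out = apply_artifact_mask(
            self._traces(), ArtifactIntervals([(100, 200)]), MaskMode.SPLIT
        )
        assert [p.n_frames for p, _ in out] == [100, 2800]
        np.testing.assert_array_equal(out[0][1], np.arange(100))
        np.testing.assert_array_equal(out[1][1], np.arange(200, 3000))

    def test_no_intervals_identity(self):
        out = apply_artifact_mask(self._traces(), ArtifactIntervals([]), MaskMode.DROP)
        assert out[0][0].n_frames == 3000

    def test_frame_conservation(self):
        iv = ArtifactIntervals([(10, 50), (100, 230), (2900, 3000)])
        for mode in (MaskMode.DROP, MaskMode.SPLIT):
            out = apply_artifact_mask(self._traces(), iv, mode)
            kept = sum(p.n_frames for p, _ in out)
            assert kept + iv.total_frames() == 3000

    def test_all_frames_flagged_rejected(self):
        with pytest.raises(ValueError, match="every frame"):
            apply_artifact_mask(
                self._traces(), ArtifactIntervals([(0, 3000)]), MaskMode.DROP
            )
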