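import itertools

import numpy as np
import pytest

from axopipe import (
    ClusterParams,
    CorrelationMatrix,
    GroundTruthGroups,
    ami_score,
    cluster_hierarchical,
    cluster_kmeans,
    correlation_matrix,
    ground_truth_groups,
    prefilter_singletons,
    scan_k,
    silhouette,
)

from conftest import make_traces


def corr_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    return CorrelationMatrix(values=values, roi_ids=ids or [str(i) for i in range(len(values))])


def block_matrix(sizes, within=0.95, between=0.05, jitter=0.005):
    n = sum(sizes)
    m = np.full((n, n), between)
    start = 0
    for s in sizes:
        m[start : start + s, start : start + s] = within
        start += s
    if jitter:  # break exact merge-height ties, as any real correlation matrix would
        rng = np.random.default_rng(12345)
        j = rng.uniform(-jitter, jitter, size=(n, n))
        m = m + np.triu(j, 1) + np.triu(j, 1).T
    np.fill_diagonal(m, 1.0)
    return corr_from(np.clip(m, -1, 1))


def brute_force_best_2partition(corr):
    """Best 2-partition by within-minus-between mean correlation."""
    n = corr.n
    best, best_score = None, -np.inf
    for size in range(1, n // 2 + 1):
        for subset in itertools.combinations(range(n), size):
            a = np.array(subset)
            b = np.array([i for i in range(n) if i not in subset])
            wa = corr.values[np.ix_(a, a)][np.triu_indices(len(a), 1)]
            wb = corr.values[np.ix_(b, b)][np.triu_indices(len(b), 1)]
            within = np.concatenate([wa, wb]).mean() if (len(a) > 1 or len(b) > 1) else 0
            between = corr.values[np.ix_(a, b)].mean()
            if within - between > best_score:
                best_score, best = within - between, frozenset(subset)
    return best


class TestCorrelationMatrix:
    def test_scaled_copy_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        corr, forced = correlation_matrix(make_traces(np.vstack([x, 2 * x])))
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert forced == []

    def test_negated_copy_anticorrelated(self):
        x = np.random.default_rng(1).standard_normal(500)
        corr, _ = correlation_matrix(make_traces(np.vstack([x, -x])))
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(2)
        corr, _ = correlation_matrix(make_traces(rng.standard_normal((2, 5000))))
        assert abs(corr.values[0, 1]) < 0.05

    def test_zero_variance_rows_forced_singleton(self):
        rng = np.random.default_rng(3)
        vals = np.vstack([rng.standard_normal((2, 100)), np.zeros(100)])
        corr, forced = correlation_matrix(make_traces(vals, roi_ids=["a", "b", "dead"]))
        assert corr.roi_ids == ["a", "b"]
        assert forced == ["dead"]


class TestPrefilter:
    def test_correlated_pair_kept_third_singleton(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        m[0, 2] = m[2, 0] = m[1, 2] = m[2, 1] = 0.1
        cand, single = prefilter_singletons(corr_from(m), 0.8)
        assert cand == [0, 1] and single == [2]

    def test_all_below_threshold_all_singletons(self):
        m = np.eye(4) * 0.5 + 0.5 * np.eye(4)
        m[m == 0] = 0.3
        cand, single = prefilter_singletons(corr_from(m), 0.8)
        assert cand == [] and len(single) == 4

    def test_all_perfectly_correlated_all_candidates(self):
        m = np.ones((4, 4))
        cand, single = prefilter_singletons(corr_from(m), 0.8)
        assert len(cand) == 4 and single == []


class TestClusteringMethods:
    def test_hierarchical_recovers_blocks_vs_brute_force(self):
        corr = block_matrix([4, 4])
        labels = cluster_hierarchical(corr, 2)
        got = frozenset(np.flatnonzero(labels == labels[0]))
        want = brute_force_best_2partition(corr)
        assert got in (want, frozenset(range(8)) - want)

    def test_kmeans_recovers_blocks_and_is_deterministic(self):
        corr = block_matrix([4, 4])
        l1 = cluster_kmeans(corr, 2, seed=1)
        l2 = cluster_kmeans(corr, 2, seed=1)
        np.testing.assert_array_equal(l1, l2)
        got = frozenset(np.flatnonzero(l1 == l1[0]))
        want = brute_force_best_2partition(corr)
        assert got in (want, frozenset(range(8)) - want)

    def test_k_equals_n_every_roi_alone(self):
        corr = block_matrix([3, 3])
        labels = cluster_hierarchical(corr, 6)
        assert len(np.unique(labels)) == 6

    def test_k_out_of_range_rejected(self):
        corr = block_matrix([2, 2])
        with pytest.raises(ValueError):
            cluster_hierarchical(corr, 5)
        with pytest.raises(ValueError):
            cluster_kmeans(corr, 1)


class TestSilhouette:
    def test_perfectly_separated_blocks_near_one(self):
        corr = block_matrix([4, 4], within=1.0, between=0.1)
        s = silhouette(corr, np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        assert s > 0.85

    def test_random_labels_on_structureless_matrix_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.4, 0.6, size=(30, 30))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        scores = [
            silhouette(corr_from(m), rng.integers(0, 2, size=30))
            for _ in range(20)
        ]
        assert abs(np.mean(scores)) < 0.05

    def test_four_point_hand_computed_value(self):
        # d(0,1)=0.1, d(2,3)=0.2, all cross distances 0.9:
        # s = mean[(0.9-0.1)/0.9 x2, (0.9-0.2)/0.9 x2] = 5/6
        m = np.array([
            [1.0, 0.9, 0.1, 0.1],
            [0.9, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.8],
            [0.1, 0.1, 0.8, 1.0],
        ])
        s = silhouette(corr_from(m), np.array([0, 0, 1, 1]))
        assert s == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError):
            silhouette(block_matrix([4]), np.zeros(4, dtype=int))


class TestAmi:
    def test_identical_partitions_and_label_permutation(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert ami_score(labels, labels) == pytest.approx(1.0)
        assert ami_score(labels, (labels + 1) % 3) == pytest.approx(1.0)

    def test_independent_partitions_chance_corrected(self):
        rng = np.random.default_rng(0)
        vals = [
            ami_score(rng.integers(0, 5, 200), rng.integers(0, 5, 200))
            for _ in range(100)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            ami_score(np.zeros(3), np.zeros(4))


class TestScanK:
    def test_planted_groups_selected_with_perfect_ami(self):
        corr = block_matrix([4, 4, 4, 4, 4], within=0.95, between=0.05)
        truth = GroundTruthGroups(
            groups=[[str(i) for i in range(g * 4, g * 4 + 4)] for g in range(5)]
        )
        results = scan_k(corr, ClusterParams(seed=0), truth=truth)
        for res in results.values():
            assert res.k == 5
            assert res.ami_at_k == pytest.approx(1.0)
            assert res.metrics_agree

    def test_structureless_matrix_warns_low_silhouette(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.75, 0.95, size=(12, 12))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        results = scan_k(corr_from(m), ClusterParams(method="hierarchical"))
        res = results["hierarchical"]
        assert max(res.silhouette_by_k.values()) < 0.25
        assert res.warning is not None

    def test_four_candidates_single_k(self):
        corr = block_matrix([2, 2])
        results = scan_k(corr, ClusterParams(method="hierarchical"))
        assert list(results["hierarchical"].silhouette_by_k) == [2]

    def test_singleton_conservation_in_full_partition(self):
        corr = block_matrix([3, 3])
        results = scan_k(
            corr, ClusterParams(method="kmeans"), singleton_ids=["s1", "s2"]
        )
        part = results["kmeans"].full_partition()
        assert set(part) == set(corr.roi_ids) | {"s1", "s2"}
        assert part["s1"] != part["s2"]


class TestGroundTruth:
    def _pair(self, ra, rb):
        def m(r):
            out = np.eye(3)
            out[0, 1] = out[1, 0] = r
            return corr_from(out)

        return m(ra), m(rb)

    def test_consistent_pair_grouped(self):
        gt = ground_truth_groups(*self._pair(0.9, 0.9))
        assert sorted(map(sorted, gt.groups)) == [["0", "1"], ["2"]]

    def test_inconsistent_pair_split(self):
        gt = ground_truth_groups(*self._pair(0.9, 0.3))
        assert all(len(g) == 1 for g in gt.groups)

    def test_chain_merged_by_connected_components(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.9
        m[1, 2] = m[2, 1] = 0.9
        m[0, 2] = m[2, 0] = 0.2
        gt = ground_truth_groups(corr_from(m.copy()), corr_from(m.copy()))
        assert sorted(map(sorted, gt.groups)) == [["0", "1", "2"]]

    def test_roi_set_mismatch_rejected(self):
        a = corr_from(np.eye(2), ids=["x", "y"])
        b = corr_from(np.eye(2), ids=["x", "z"])
        with pytest.raises(ValueError):
            ground_truth_groups(a, b)
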