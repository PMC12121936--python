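"""Grouping ROIs that belong to the same axon or dendrite.

Branches of one axon carry the same spike train, so their ROIs coactivate:
the zero-lag Pearson correlation between their transient-masked ΔF/F
traces is high. Grouping proceeds in three steps:

1. *Prefilter.* An ROI whose maximum correlation with every other ROI is
   at or below ``prefilter_r`` (default 0.8) cannot be part of a
   multi-ROI group; it becomes a singleton and is excluded from
   clustering.
2. *Cluster.* The remaining candidates are clustered — agglomerative with
   average linkage on the dissimilarity ``1 − r``, and k-means on the rows
   of the correlation matrix (each ROI's correlation profile as its
   feature vector) — for every cluster count ``k`` from 2 up to half the
   candidate count.
3. *Model selection.* The ``k`` maximizing the mean Silhouette score
   (dissimilarity ``1 − r`` for both methods, so scores are comparable)
   is chosen. When a ground-truth partition is available, the Adjusted
   Mutual Information (AMI) against it is also scanned, and agreement of
   the two argmax ``k`` values is reported — in practice Silhouette alone
   suffices.

Ground truth can be constructed from paired recordings of the same ROIs in
two distinct environments: hippocampal place fields remap across
environments, so two ROIs whose pairwise correlation stays above 0.7 in
*both* environments almost certainly share a parent cell. Such
consistently correlated pairs are merged into groups by connected
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, silhouette_score as _sk_silhouette

from .io import TraceMatrix

__all__ = [
    "ClusterParams",
    "CorrelationMatrix",
    "ClusterResult",
    "GroundTruthGroups",
    "correlation_matrix",
    "prefilter_singletons",
    "cluster_hierarchical",
    "cluster_kmeans",
    "silhouette",
    "ami_score",
    "scan_k",
    "ground_truth_groups",
]

Linkage = Literal["single", "complete", "average", "ward"]


@dataclass(frozen=True)
class ClusterParams:
    """Prefilter threshold, K-scan range, method and seed."""

    prefilter_r: float = 0.8
    k_min: int = 2
    k_max_fraction: float = 0.5
    method: Literal["hierarchical", "kmeans", "both"] = "both"
    linkage: Linkage = "average"
    n_init: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.prefilter_r < 1:
            raise ValueError("prefilter_r must be in (-1, 1)")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if not 0 < self.k_max_fraction <= 0.5:
            raise ValueError("k_max_fraction must be in (0, 0.5]")


@dataclass
class CorrelationMatrix:
    """Symmetric zero-lag Pearson correlation between ROI pairs."""

    values: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if len(self.roi_ids) != v.shape[0]:
            raise ValueError("roi_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal must be 1")
        if v.size and (v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, indices: list[int]) -> "CorrelationMatrix":
        idx = np.asarray(indices)
        return CorrelationMatrix(
            values=self.values[np.ix_(idx, idx)],
            roi_ids=[self.roi_ids[i] for i in indices],
        )


@dataclass
class ClusterResult:
    """Group labels for candidate ROIs plus the K-scan diagnostics."""

    roi_ids: list[str]  # candidate ROIs, clustering order
    labels: np.ndarray
    singletons: list[str]
    k: int
    method: str
    silhouette_by_k: dict[int, float]
    ami_by_k: dict[int, float] | None = None
    ami_at_k: float | None = None
    warning: str | None = None

    @property
    def best_ami_k(self) -> int | None:
        if not self.ami_by_k:
            return None
        return max(self.ami_by_k, key=self.ami_by_k.get)

    @property
    def metrics_agree(self) -> bool | None:
        """Does the Silhouette-optimal k match the AMI-optimal k?"""
        if self.ami_by_k is None:
            return None
        return self.k == self.best_ami_k

    def full_partition(self) -> dict[str, int]:
        """Labels over candidates and singletons (each singleton its own group)."""
        out = {r: int(l) for r, l in zip(self.roi_ids, self.labels)}
        next_label = (int(self.labels.max()) + 1) if self.labels.size else 0
        for i, r in enumerate(self.singletons):
            out[r] = next_label + i
        return out


@dataclass
class GroundTruthGroups:
    """Partition of ROI ids into putative same-axon groups."""

    groups: list[list[str]]

    def __post_init__(self) -> None:
        flat = [r for g in self.groups for r in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups must be disjoint")

    def roi_ids(self) -> list[str]:
        return [r for g in self.groups for r in g]

    def labels_for(self, roi_ids: list[str]) -> np.ndarray:
        mapping = {r: gi for gi, g in enumerate(self.groups) for r in g}
        missing = [r for r in roi_ids if r not in mapping]
        if missing:
            raise ValueError(f"ROIs missing from ground truth: {missing[:5]}")
        return np.array([mapping[r] for r in roi_ids])


def correlation_matrix(masked_dff: TraceMatrix) -> tuple[CorrelationMatrix, list[str]]:
    """Pairwise zero-lag Pearson correlation over all frames.

    Zero-variance ROIs (typically all-zero masked traces with no detected
    transients) cannot be correlated; they are excluded from the matrix and
    returned separately as forced singletons.
    """
    if masked_dff.n_rois < 2:
        raise ValueError("need at least 2 ROIs for a correlation matrix")
    sd = masked_dff.values.std(axis=1)
    keep = np.flatnonzero(sd > 0)
    forced = [masked_dff.roi_ids[i] for i in np.flatnonzero(sd == 0)]
    if keep.size < 2:
        raise ValueError("fewer than 2 ROIs with nonzero variance; nothing to correlate")
    corr = np.corrcoef(masked_dff.values[keep])
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return (
        CorrelationMatrix(values=corr, roi_ids=[masked_dff.roi_ids[i] for i in keep]),
        forced,
    )


def prefilter_singletons(
    corr: CorrelationMatrix, prefilter_r: float = 0.8
) -> tuple[list[int], list[int]]:
    """Split ROIs into clustering candidates and singletons.

    A ROI is a candidate iff its maximum off-diagonal correlation strictly
    exceeds ``prefilter_r``; all others are singletons (final groups of one).
    Returns (candidate indices, singleton indices) into ``corr``.
    """
    v = corr.values.copy()
    np.fill_diagonal(v, -np.inf)
    max_r = v.max(axis=1)
    candidates = [i for i in range(corr.n) if max_r[i] > prefilter_r]
    singletons = [i for i in range(corr.n) if max_r[i] <= prefilter_r]
    return candidates, singletons


def _check_k(k: int, n: int) -> None:
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")


def cluster_hierarchical(
    corr: CorrelationMatrix, k: int, linkage_method: Linkage = "average"
) -> np.ndarray:
    """Agglomerative clustering on dissimilarity 1 − r, cut at k clusters."""
    _check_k(k, corr.n)
    dist = np.clip(1.0 - corr.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    return fcluster(Z, t=k, criterion="maxclust") - 1


def cluster_kmeans(corr: CorrelationMatrix, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """K-means on correlation profiles (rows of the correlation matrix)."""
    _check_k(k, corr.n)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(corr.values)


def silhouette(corr: CorrelationMatrix, labels: np.ndarray) -> float:
    """Mean silhouette over ROIs with dissimilarity 1 − r."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    dist = np.clip(1.0 - corr.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return float(_sk_silhouette(dist, labels, metric="precomputed"))


def ami_score(labels: np.ndarray, truth_labels: np.ndarray) -> float:
    """Adjusted Mutual Information between two labelings of the same ROIs.

    Chance-corrected under the permutation model: 1 for identical
    partitions (up to label renaming), ~0 for independent ones.
    """
    labels, truth_labels = np.asarray(labels), np.asarray(truth_labels)
    if labels.shape != truth_labels.shape:
        raise ValueError("labelings must cover the same ROI set")
    return float(adjusted_mutual_info_score(truth_labels, labels))


_LOW_STRUCTURE_SILHOUETTE = 0.25


def scan_k(
    corr: CorrelationMatrix,
    params: ClusterParams | None = None,
    truth: GroundTruthGroups | None = None,
    singleton_ids: list[str] | None = None,
) -> dict[str, ClusterResult]:
    """Scan cluster counts and pick the Silhouette-optimal partition.

    For each method requested in ``params.method`` and each
    ``k`` in ``[k_min, floor(k_max_fraction x n_candidates)]``, clusters the
    candidates and scores the partition; the chosen ``k`` maximizes the
    Silhouette score. With ground truth, AMI is scanned alongside (over
    candidates plus singletons, each singleton its own group in both
    partitions) and each result reports whether the two optima agree.
    Returns one :class:`ClusterResult` per method.
    """
    params = params or ClusterParams()
    singleton_ids = singleton_ids or []
    n = corr.n
    if n < 4:
        raise ValueError(f"need >= 4 candidate ROIs to scan k, got {n}")
    k_max = int(np.floor(params.k_max_fraction * n))
    ks = list(range(params.k_min, k_max + 1))
    if not ks:
        raise ValueError(
            f"empty k range [{params.k_min}, {k_max}] for {n} candidates"
        )

    truth_full = None
    if truth is not None:
        truth_full = truth.labels_for(corr.roi_ids + singleton_ids)

    methods = ["hierarchical", "kmeans"] if params.method == "both" else [params.method]
    results: dict[str, ClusterResult] = {}
    for method in methods:
        sil_by_k: dict[int, float] = {}
        ami_by_k: dict[int, float] | None = {} if truth is not None else None
        labels_by_k: dict[int, np.ndarray] = {}
        for k in ks:
            if method == "hierarchical":
                labels = cluster_hierarchical(corr, k, params.linkage)
            else:
                labels = cluster_kmeans(corr, k, params.seed, params.n_init)
            if len(np.unique(labels)) < 2:
                # tied merge heights can collapse a hierarchical cut; skip this k
                continue
            labels_by_k[k] = labels
            sil_by_k[k] = silhouette(corr, labels)
            if truth_full is not None:
                # singletons appended as their own clusters in the test partition
                extended = np.concatenate(
                    [labels, labels.max() + 1 + np.arange(len(singleton_ids))]
                )
                ami_by_k[k] = ami_score(extended, truth_full)
        if not sil_by_k:
            raise ValueError(
                f"{method}: no k in [{params.k_min}, {k_max}] produced >= 2 clusters"
            )
        best_k = max(sil_by_k, key=sil_by_k.get)
        warning = None
        if sil_by_k[best_k] < _LOW_STRUCTURE_SILHOUETTE:
            warning = (
                f"max silhouette {sil_by_k[best_k]:.3f} < {_LOW_STRUCTURE_SILHOUETTE}: "
                "correlation structure too weak to support grouping"
            )
        results[method] = ClusterResult(
            roi_ids=list(corr.roi_ids),
            labels=labels_by_k[best_k],
            singletons=list(singleton_ids),
            k=len(np.unique(labels_by_k[best_k])),
            method=method,
            silhouette_by_k=sil_by_k,
            ami_by_k=ami_by_k,
            ami_at_k=(ami_by_k or {}).get(best_k),
            warning=warning,
        )
    return results


def ground_truth_groups(
    corr_env_a: CorrelationMatrix,
    corr_env_b: CorrelationMatrix,
    threshold: float = 0.7,
) -> GroundTruthGroups:
    """Same-axon groups from correlations consistent across two environments.

    An edge joins ROIs i and j iff their pairwise correlation exceeds
    ``threshold`` in *both* environments; groups are the connected
    components of that graph (singletons included). Transitive closure is
    used because a partition must be consistent: if i-j and j-k are each
    consistently correlated, all three are assigned to one group even when
    the i-k correlation falls short.
    """
    if corr_env_a.roi_ids != corr_env_b.roi_ids:
        raise ValueError("the two environments must cover the same ROI set, same order")
    adj = (corr_env_a.values > threshold) & (corr_env_b.values > threshold)
    np.fill_diagonal(adj, False)
    n = corr_env_a.n
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(adj, directed=False)
    groups = [[] for _ in range(n_comp)]
    for i in range(n):
        groups[comp[i]].append(corr_env_a.roi_ids[i])
    return GroundTruthGroups(groups=groups)
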