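"""Clusterer correctness against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from smlm_bayescluster import (
    cluster_dbscan,
    cluster_ripley,
    cluster_tomato,
    make_table,
    neighbor_counts,
)
from smlm_bayescluster.clusterers import canonical_labels


def _table_from_xy(xy):
    return make_table(xy[:, 0], xy[:, 1], np.full(len(xy), 10.0))


def _partition_sets(labels, subset=None):
    """Frozenset-of-frozensets view of a labeling, optionally restricted."""
    idx = np.arange(len(labels)) if subset is None else np.flatnonzero(subset)
    groups = {}
    for i in idx:
        if labels[i] > 0:
            groups.setdefault(labels[i], set()).add(int(i))
    return frozenset(frozenset(g) for g in groups.values())


# ---------------------------------------------------------------------------
# independent oracles (plain O(n^2) python)


def brute_dbscan(xy, eps, min_pts):
    d = cdist(xy, xy)
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts  # includes the point itself
    labels = np.zeros(len(xy), dtype=int)
    cid = 0
    for i in range(len(xy)):
        if labels[i] or not core[i]:
            continue
        cid += 1
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == 0:
                    labels[k] = cid
                    stack.append(k)
    return labels, core


def brute_ripley(xy, r, T):
    d = cdist(xy, xy)
    counts = (d <= r).sum(axis=1) - 1
    mask = counts >= T
    labels = np.zeros(len(xy), dtype=int)
    cid = 0
    for i in np.flatnonzero(mask):
        if labels[i]:
            continue
        cid += 1
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(mask & (d[j] <= r)):
                if labels[k] == 0:
                    labels[k] = cid
                    stack.append(k)
    return labels


def brute_tomato(xy, r, tau):
    """Exhaustive union-find trace of the persistence sweep."""
    d = cdist(xy, xy)
    adj = (d <= r) & ~np.eye(len(xy), dtype=bool)
    dens = adj.sum(axis=1).astype(float)
    n = len(xy)
    order = sorted(range(n), key=lambda i: (-dens[i], i))
    rank = {i: p for p, i in enumerate(order)}
    parent = {}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    peak = {}
    processed = set()
    for i in order:
        nb = [j for j in np.flatnonzero(adj[i]) if j in processed]
        if not nb:
            parent[i] = i
            peak[i] = dens[i]
            processed.add(i)
            continue
        g = min(nb, key=lambda j: rank[j])  # highest density, ties lower index
        ri = find(g)
        for j in nb:
            rj = find(j)
            ri = find(ri)
            if ri == rj:
                continue
            if (peak[ri], -rank[ri]) >= (peak[rj], -rank[rj]):
                hi, lo = ri, rj
            else:
                hi, lo = rj, ri
            if peak[lo] - dens[i] < tau:
                parent[lo] = hi
                ri = hi
        parent[i] = ri
        processed.add(i)
    out = np.zeros(n, dtype=int)
    for i in range(n):
        r_ = find(i)
        out[i] = r_ + 1 if peak[r_] >= tau else 0
    return canonical_labels(out)


# ---------------------------------------------------------------------------


def test_neighbor_counts_trivial_cases():
    single = _table_from_xy(np.array([[0.0, 0.0]]))
    assert neighbor_counts(single, 50.0).tolist() == [0]
    pair = _table_from_xy(np.array([[0.0, 0.0], [10.0, 0.0]]))
    assert neighbor_counts(pair, 20.0).tolist() == [1, 1]


def test_neighbor_counts_match_brute_force(rng):
    xy = rng.uniform(0, 1000, size=(50, 2))
    counts = neighbor_counts(_table_from_xy(xy), 100.0)
    d = cdist(xy, xy)
    expected = (d <= 100.0).sum(axis=1) - 1
    np.testing.assert_array_equal(counts, expected)


class TestRipley:
    def test_threshold_above_n_means_all_background(self, rng):
        xy = rng.uniform(0, 500, size=(20, 2))
        labels = cluster_ripley(_table_from_xy(xy), 1000.0, T=20)
        assert np.all(labels == 0)

    def test_seven_point_toy_instance(self):
        # two 60-nm triads 400 nm apart and one stray point
        triad = np.array([[0.0, 0.0], [60.0, 0.0], [30.0, 50.0]])
        xy = np.vstack([triad, triad + [400.0, 0.0], [[200.0, 300.0]]])
        labels = cluster_ripley(_table_from_xy(xy), 80.0, T=2)
        assert labels.tolist() == [1, 1, 1, 2, 2, 2, 0]

    def test_nearby_clusters_merge_at_large_radius(self, rng):
        a = rng.normal([1000.0, 1000.0], 50.0, size=(100, 2))
        b = rng.normal([1120.0, 1000.0], 50.0, size=(100, 2))
        labels = cluster_ripley(_table_from_xy(np.vstack([a, b])), 150.0, T=5)
        clustered = labels[labels > 0]
        assert len(np.unique(clustered)) == 1  # fails to separate the pair

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 600, size=(60, 2))
        r, T = rng.uniform(30, 150), rng.integers(1, 8)
        labels = cluster_ripley(_table_from_xy(xy), r, int(T))
        expected = brute_ripley(xy, r, int(T))
        assert _partition_sets(labels) == _partition_sets(expected)


class TestDBSCAN:
    def test_min_pts_above_n_all_noise(self, rng):
        xy = rng.uniform(0, 500, size=(15, 2))
        labels = cluster_dbscan(_table_from_xy(xy), 1000.0, 16)
        assert np.all(labels == 0)

    def test_two_blob_instance_matches_reference(self):
        rng = np.random.default_rng(42)
        a = rng.normal([0.0, 0.0], 20.0, size=(10, 2))
        b = rng.normal([500.0, 0.0], 20.0, size=(10, 2))
        xy = np.vstack([a, b])
        labels = cluster_dbscan(_table_from_xy(xy), 60.0, 5)
        expected, core = brute_dbscan(xy, 60.0, 5)
        assert len(np.unique(labels[labels > 0])) == 2
        assert _partition_sets(labels, core) == _partition_sets(expected, core)
        np.testing.assert_array_equal(labels == 0, expected == 0)

    def test_duplicate_points_form_one_cluster(self):
        xy = np.zeros((6, 2))
        labels = cluster_dbscan(_table_from_xy(xy), 10.0, 5)
        assert np.all(labels == 1)

    @pytest.mark.parametrize("seed", range(100))
    def test_partition_matches_brute_force_on_random_instances(self, seed):
        """Core-point partition and noise set equal the textbook reference."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        xy = np.vstack(
            [
                rng.normal(rng.uniform(0, 800, 2), rng.uniform(10, 60), size=(n // 2, 2)),
                rng.uniform(0, 800, size=(n - n // 2, 2)),
            ]
        )
        eps = float(rng.uniform(20, 120))
        min_pts = int(rng.integers(2, 8))
        labels = cluster_dbscan(_table_from_xy(xy), eps, min_pts)
        expected, core = brute_dbscan(xy, eps, min_pts)
        assert _partition_sets(labels, core) == _partition_sets(expected, core)
        np.testing.assert_array_equal(labels == 0, expected == 0)

    def test_agrees_with_sklearn_cross_check(self):
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(3)
        xy = np.vstack(
            [
                rng.normal([200, 200], 30, size=(40, 2)),
                rng.normal([700, 600], 30, size=(40, 2)),
                rng.uniform(0, 900, size=(30, 2)),
            ]
        )
        labels = cluster_dbscan(_table_from_xy(xy), 60.0, 6)
        sk = DBSCAN(eps=60.0, min_samples=6).fit(xy)
        core = np.zeros(len(xy), bool)
        core[sk.core_sample_indices_] = True
        assert _partition_sets(labels, core) == _partition_sets(sk.labels_ + 1, core)
        np.testing.assert_array_equal(labels == 0, sk.labels_ == -1)


class TestToMATo:
    def test_tau_above_max_density_gives_background(self, rng):
        xy = rng.uniform(0, 400, size=(30, 2))
        labels = cluster_tomato(_table_from_xy(xy), 100.0, 1e6)
        assert np.all(labels == 0)

    def test_row_permutation_invariance(self, rng):
        xy = np.vstack(
            [
                rng.normal([300, 300], 30, size=(50, 2)),
                rng.normal([600, 500], 30, size=(50, 2)),
                rng.uniform(0, 900, size=(20, 2)),
            ]
        )
        labels = cluster_tomato(_table_from_xy(xy), 60.0, 3.0)
        perm = rng.permutation(len(xy))
        permuted = cluster_tomato(_table_from_xy(xy[perm]), 60.0, 3.0)
        back = np.zeros_like(permuted)
        back[perm] = permuted
        assert _partition_sets(labels) == _partition_sets(back)

    def test_two_blobs_and_merge_decisions_match_trace_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal([300.0, 300.0], 30.0, size=(100, 2))
        b = rng.normal([500.0, 300.0], 30.0, size=(100, 2))
        xy = np.vstack([a, b])
        labels = cluster_tomato(_table_from_xy(xy), 50.0, 10.0)
        assert len(np.unique(labels[labels > 0])) == 2
        np.testing.assert_array_equal(labels, brute_tomato(xy, 50.0, 10.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_trace_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        xy = np.vstack(
            [
                rng.normal(rng.uniform(100, 700, 2), 40, size=(40, 2)),
                rng.normal(rng.uniform(100, 700, 2), 40, size=(40, 2)),
                rng.uniform(0, 800, size=(20, 2)),
            ]
        )
        r = float(rng.uniform(30, 100))
        tau = float(rng.integers(1, 15))
        np.testing.assert_array_equal(
            cluster_tomato(_table_from_xy(xy), r, tau), brute_tomato(xy, r, tau)
        )

    def test_cluster_count_non_increasing_in_tau(self, benchmark_table):
        counts = [
            len(np.unique(cluster_tomato(benchmark_table, 50.0, tau))) - 1
            for tau in (1.0, 5.0, 15.0, 40.0, 80.0, 200.0)
        ]
        assert counts == sorted(counts, reverse=True)
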