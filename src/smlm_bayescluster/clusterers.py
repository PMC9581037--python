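"""Proposal-generating cluster algorithms.

All three clusterers map a localization table and a (radius, threshold)
pair to an integer labeling (0 = background/noise, clusters 1..K numbered
by first appearance in row order).  They share one primitive: the exact
Euclidean fixed-radius neighbor graph, built with a k-d tree but bit-for-bit
equivalent to brute force.  Localization precision is deliberately ignored
here — it enters only the Bayesian score.

* ``ripley``  — per-point neighbor counts are thresholded at T and the
  surviving points joined by r-connectivity (a localization-level reading of
  Ripley's K: points whose r-neighborhood is unusually populated).
* ``dbscan``  — classic DBSCAN with eps = r and minPts = T (core test
  counts the point itself); border points join the cluster of their
  lowest-index core neighbor.
* ``tomato``  — persistence-guided mode seeking (ToMATo): density = raw
  neighbor count at radius r, peaks found by a union-find sweep in
  decreasing density, peaks whose prominence is below tau merged into their
  higher neighbor, surviving peaks below tau discarded as background.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .types import ValidationError

__all__ = [
    "NeighborGraph",
    "build_neighbor_graph",
    "neighbor_counts",
    "cluster_ripley",
    "cluster_dbscan",
    "cluster_tomato",
    "canonical_labels",
]


class NeighborGraph:
    """Symmetric fixed-radius adjacency of a point set, in CSR form.

    ``indices[indptr[i]:indptr[i+1]]`` are the neighbors of point i within
    ``r_nm`` (self excluded), sorted ascending.  ``counts`` is the per-point
    neighbor count, i.e. the raw density estimate shared by all clusterers.
    """

    def __init__(self, xy: np.ndarray, r_nm: float):
        if r_nm <= 0:
            raise ValidationError("r_nm must be > 0")
        self.r_nm = float(r_nm)
        n = len(xy)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r_nm, output_type="ndarray")
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        order = np.lexsort((cols, rows))
        rows, cols = rows[order], cols[order]
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self.indptr, rows + 1, 1)
        np.cumsum(self.indptr, out=self.indptr)
        self.indices = cols.astype(np.int64)
        self.counts = np.diff(self.indptr).astype(np.int64)
        self.n = n
        self._adj = sparse.csr_matrix(
            (np.ones(len(self.indices), dtype=np.int8), self.indices, self.indptr),
            shape=(n, n),
        )

    def subgraph_components(self, mask: np.ndarray) -> np.ndarray:
        """Connected-component id (within the masked subgraph) per masked point;
        -1 for points outside the mask."""
        comp = np.full(self.n, -1, dtype=np.int64)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return comp
        sub = self._adj[idx][:, idx]
        _, lab = connected_components(sub, directed=False)
        comp[idx] = lab
        return comp


def build_neighbor_graph(table, r_nm: float) -> NeighborGraph:
    xy = np.column_stack([table["x_nm"].to_numpy(), table["y_nm"].to_numpy()])
    return NeighborGraph(xy, r_nm)


def neighbor_counts(table, r_nm: float) -> np.ndarray:
    """Number of other localizations within r_nm of each localization."""
    return build_neighbor_graph(table, r_nm).counts


def canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber nonzero labels to 1..K by first appearance in row order."""
    out = np.zeros(len(raw), dtype=np.int32)
    mapping: dict[int, int] = {}
    nz = np.flatnonzero(raw > 0) if raw.dtype != bool else np.flatnonzero(raw)
    for i in nz:
        v = int(raw[i])
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


# ---------------------------------------------------------------------------
# Ripley's-K-based


def ripley_labels(graph: NeighborGraph, T: int) -> np.ndarray:
    mask = graph.counts >= T
    comp = graph.subgraph_components(mask)
    return canonical_labels(comp + 1)


def cluster_ripley(table, r_nm: float, T: int) -> np.ndarray:
    """Threshold neighbor counts at T, join survivors by r-connectivity."""
    if T < 1:
        raise ValidationError("T must be >= 1")
    return ripley_labels(build_neighbor_graph(table, r_nm), int(T))


# ---------------------------------------------------------------------------
# DBSCAN


def dbscan_labels(graph: NeighborGraph, min_pts: int) -> np.ndarray:
    core = graph.counts + 1 >= min_pts  # neighbor count includes the point itself
    comp = graph.subgraph_components(core)
    raw = comp + 1  # provisional labels on core points
    # border points: lowest-index core neighbor decides the cluster
    if np.any(core) and not np.all(core):
        rows = np.repeat(np.arange(graph.n), np.diff(graph.indptr))
        cols = graph.indices
        sel = (~core[rows]) & core[cols]
        nearest = np.full(graph.n, graph.n, dtype=np.int64)
        np.minimum.at(nearest, rows[sel], cols[sel])
        border = np.flatnonzero((nearest < graph.n) & (~core))
        raw[border] = comp[nearest[border]] + 1
    return canonical_labels(raw)


def cluster_dbscan(table, r_nm: float, min_pts: int) -> np.ndarray:
    """Standard DBSCAN with eps = r_nm; noise labeled 0."""
    if min_pts < 1:
        raise ValidationError("minPts must be >= 1")
    return dbscan_labels(build_neighbor_graph(table, r_nm), int(min_pts))


# ---------------------------------------------------------------------------
# ToMATo


@njit(cache=True)
def _tomato_sweep(indptr, indices, dens, order, tau):  # pragma: no cover - jit
    n = len(dens)
    parent = np.full(n, -1, dtype=np.int64)
    peak = np.zeros(n, dtype=np.float64)
    processed = np.zeros(n, dtype=np.bool_)
    rank_of = np.empty(n, dtype=np.int64)  # position in processing order
    for pos in range(n):
        rank_of[order[pos]] = pos

    for pos in range(n):
        i = order[pos]
        # gradient neighbor: processed neighbor of maximal density
        # (ties: the one processed earlier, i.e. lower row index)
        g = -1
        g_rank = n
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if processed[j] and rank_of[j] < g_rank:
                g_rank = rank_of[j]
                g = j
        if g < 0:
            parent[i] = i
            peak[i] = dens[i]
            processed[i] = True
            continue
        # find root of the gradient cluster
        ri = g
        while parent[ri] != ri:
            ri = parent[ri]
        # merge adjacent clusters with sub-tau prominence at this saddle
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            if not processed[j]:
                continue
            rj = j
            while parent[rj] != rj:
                rj = parent[rj]
            while parent[ri] != ri:
                ri = parent[ri]
            if ri == rj:
                continue
            # higher peak wins; ties go to the earlier-processed root
            if peak[ri] > peak[rj] or (peak[ri] == peak[rj] and rank_of[ri] < rank_of[rj]):
                hi, lo = ri, rj
            else:
                hi, lo = rj, ri
            if peak[lo] - dens[i] < tau:
                parent[lo] = hi
                ri = hi
        parent[i] = ri
        processed[i] = True

    # resolve roots, discard clusters whose peak density is below tau
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        r = i
        while parent[r] != r:
            r = parent[r]
        out[i] = r + 1 if peak[r] >= tau else 0
    return out


def tomato_labels(graph: NeighborGraph, tau: float, dens: np.ndarray | None = None) -> np.ndarray:
    if dens is None:
        dens = graph.counts.astype(np.float64)
    else:
        dens = np.asarray(dens, dtype=np.float64)
    if np.all(dens < tau):
        return np.zeros(graph.n, dtype=np.int32)
    # decreasing density, ties by lower row index
    order = np.lexsort((np.arange(graph.n), -dens))
    raw = _tomato_sweep(graph.indptr, graph.indices, dens, order, float(tau))
    return canonical_labels(raw)


def cluster_tomato(table, r_nm: float, tau: float) -> np.ndarray:
    """Persistence-guided mode seeking with density = neighbor count at r_nm.

    tau is the persistence threshold in density (neighbor-count) units:
    candidate peaks whose prominence (peak density minus density at the
    saddle where they meet a stronger cluster) falls below tau are merged,
    and surviving clusters whose peak density is below tau are discarded as
    background.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    return tomato_labels(build_neighbor_graph(table, r_nm), float(tau))


CLUSTERERS = {
    "ripley": cluster_ripley,
    "dbscan": cluster_dbscan,
    "tomato": cluster_tomato,
}
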