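"""Aggregate segmentation via an approximate Euclidean minimum spanning tree.

Pooled localizations from the whole movie are connected by a minimum
spanning tree built on a k-nearest-neighbor candidate graph (k = 30 by
default).  Cutting every edge longer than the 95th percentile of edge
lengths separates high-density aggregate regions from sparse
background; clusters below 100 points are discarded.  Per frame, each
aggregate's cumulative point set is re-refined with a smaller tree
(k = 10, 400 nm hard cutoff) and the largest connected subgroup is the
aggregate for that frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree
from sklearn.neighbors import kneighbors_graph

from .io_render import LocalizationTable

__all__ = [
    "SpatialGraph",
    "AggregateCluster",
    "FrameMembership",
    "build_knn_emst",
    "cut_tree_at_percentile",
    "filter_clusters",
    "frame_membership",
    "segment",
]


@dataclass
class SpatialGraph:
    """Undirected spatial graph over localization indices.

    edges is an (m, 2) int array of node pairs (i < j), lengths the
    matching Euclidean edge lengths in nm.  For a spanning tree,
    m = n_nodes - 1 per connected component.
    """

    n_nodes: int
    edges: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(-1)
        if len(self.edges) != len(self.lengths):
            raise ValueError("edges/lengths length mismatch")
        if len(self.edges) and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")

    @property
    def total_weight(self) -> float:
        return float(self.lengths.sum())


@dataclass
class AggregateCluster:
    """A segmented aggregate: its member localization indices."""

    cluster_id: int
    members: np.ndarray
    bbox_nm: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)
        if len(np.unique(self.members)) != len(self.members):
            raise ValueError("cluster members must be unique")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class FrameMembership:
    """Per-frame retained subset of a cluster's cumulative members."""

    cluster_id: int
    frame: int
    retained: np.ndarray

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.retained)


def build_knn_emst(points: np.ndarray, k: int = 30) -> SpatialGraph:
    """Approximate Euclidean MST on the symmetrized k-NN candidate graph.

    An edge is a candidate if either endpoint lists the other among its
    k nearest neighbors.  If the candidate graph is disconnected, the
    components are bridged by their mutually nearest point pair before
    spanning, so the result is always a single spanning tree.  With
    k >= n - 1 this is the exact Euclidean MST.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n == 0:
        raise ValueError("need at least one point")
    if n == 1:
        return SpatialGraph(1, np.empty((0, 2)), np.empty(0))
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, n - 1)
    G = kneighbors_graph(pts, n_neighbors=k_eff, mode="distance")
    G = G.maximum(G.T)  # symmetrize: keep edge if either endpoint proposes it

    # bridge candidate-graph components so the MST spans everything
    extra_rows, extra_cols, extra_vals = [], [], []
    n_comp, labels = connected_components(G, directed=False)
    while n_comp > 1:
        sizes = np.bincount(labels)
        a = int(np.argmin(sizes))
        idx_a = np.flatnonzero(labels == a)
        idx_b = np.flatnonzero(labels != a)
        tree_b = cKDTree(pts[idx_b])
        d, j = tree_b.query(pts[idx_a])
        best = int(np.argmin(d))
        i_glob, j_glob = int(idx_a[best]), int(idx_b[j[best]])
        extra_rows += [i_glob, j_glob]
        extra_cols += [j_glob, i_glob]
        extra_vals += [float(d[best])] * 2
        labels[labels == a] = labels[j_glob]
        n_comp -= 1
    if extra_rows:
        G = G + coo_matrix((extra_vals, (extra_rows, extra_cols)), shape=(n, n))

    mst = minimum_spanning_tree(G).tocoo()
    i, j, w = mst.row, mst.col, mst.data
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    order = np.lexsort((hi, lo))
    return SpatialGraph(n, np.column_stack([lo, hi])[order], w[order])


def _components_to_clusters(
    n_nodes: int, edges: np.ndarray, keep: np.ndarray, points: np.ndarray,
) -> list[np.ndarray]:
    kept = edges[keep]
    if len(kept):
        adj = coo_matrix(
            (np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n_nodes, n_nodes)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n_nodes)
    return [np.flatnonzero(labels == lab) for lab in np.unique(labels)]


def cut_tree_at_percentile(
    graph: SpatialGraph, points: np.ndarray, percentile: float = 95.0,
) -> list[AggregateCluster]:
    """Cut the spanning forest at an edge-length percentile.

    Every edge strictly longer than the linear-interpolation percentile
    of all edge lengths is removed; the surviving connected components
    are the aggregate candidates.
    """
    pts = np.asarray(points, dtype=float)
    if len(graph.lengths) == 0:
        comps = [np.arange(graph.n_nodes)] if graph.n_nodes == 1 else [
            np.array([i]) for i in range(graph.n_nodes)
        ]
    else:
        thr = np.percentile(graph.lengths, percentile)  # linear interpolation
        comps = _components_to_clusters(
            graph.n_nodes, graph.edges, graph.lengths <= thr, pts
        )
    clusters = []
    for cid, members in enumerate(comps):
        p = pts[members]
        clusters.append(AggregateCluster(
            cid, members,
            (float(p[:, 0].min()), float(p[:, 1].min()),
             float(p[:, 0].max()), float(p[:, 1].max())),
        ))
    return clusters


def filter_clusters(
    clusters: list[AggregateCluster], min_size: int = 100,
) -> list[AggregateCluster]:
    """Keep clusters with >= min_size members; re-index deterministically.

    Order: descending size, then ascending first-member index.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [c for c in clusters if len(c) >= min_size]
    kept.sort(key=lambda c: (-len(c), int(c.members.min()) if len(c) else 0))
    return [
        AggregateCluster(i, c.members, c.bbox_nm) for i, c in enumerate(kept)
    ]


def frame_membership(
    cluster: AggregateCluster,
    table: LocalizationTable,
    frame: int,
    k: int = 10,
    cutoff: float = 400.0,
) -> FrameMembership:
    """Refine a cluster's cumulative point set at one frame.

    Takes the cluster members detected at or before ``frame``, rebuilds
    the k-NN approximate EMST, deletes edges longer than ``cutoff`` nm,
    and returns the largest connected subgroup (ties broken by earliest
    first-detection frame, then lowest member index).
    """
    members = cluster.members[table.frame[cluster.members] <= frame]
    if len(members) == 0:
        return FrameMembership(cluster.cluster_id, frame, np.empty(0, dtype=np.int64))
    if len(members) == 1:
        return FrameMembership(cluster.cluster_id, frame, members)
    pts = table.points[members]
    graph = build_knn_emst(pts, k=k)
    comps = _components_to_clusters(
        graph.n_nodes, graph.edges, graph.lengths <= cutoff, pts
    )

    def sort_key(local_idx: np.ndarray):
        glob = members[local_idx]
        return (-len(local_idx), int(table.frame[glob].min()), int(glob.min()))

    best = min(comps, key=sort_key)
    return FrameMembership(cluster.cluster_id, frame, members[best])


def segment(
    table: LocalizationTable,
    k: int = 30,
    percentile: float = 95.0,
    min_size: int = 100,
) -> list[AggregateCluster]:
    """Full-movie segmentation: EMST -> percentile cut -> size filter."""
    graph = build_knn_emst(table.points, k=k)
    clusters = cut_tree_at_percentile(graph, table.points, percentile)
    return filter_clusters(clusters, min_size)
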