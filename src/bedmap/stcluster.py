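"""Two-phase spatio-temporal clustering.

Phase 1 applies Ward agglomerative clustering to the place-vector series,
grouping windows by *where* on the bed activity happened.  The label series
is then segmented into outer intervals of fixed length, each split into
``n_sub`` equal sub-intervals; the phase-1 cluster occupying the majority of
each sub-interval becomes its *representative*.  Consecutive representatives
define one edge-weighted directed transition graph per interval — edge
(i, j) counts sub-interval steps from cluster i to cluster j, with the last
step of an interval wrapping to the first representative of the next
interval, so every graph's edge weights sum to exactly ``n_sub``.  Phase 2
applies Ward clustering to the graphs' adjacency matrices (Frobenius /
flattened-Euclidean distance), grouping intervals by *how* activity moved
between spatial patterns.

The Ward implementation is in-package: an agglomerative loop on the
Lance–Williams recurrence over squared Ward distances, halting when the
requested number of clusters remains.  Merge ties are broken by the
lexicographically smallest pair of cluster ids (original points are ids
``0..m-1`` in input order; the cluster created by merge ``t`` gets id
``m+t``), making the whole procedure deterministic.  Merge heights follow
the convention ``d(u, v) = sqrt(2 |u| |v| / (|u| + |v|)) * ||c_u - c_v||``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .placevec import PlaceVectorSeries

__all__ = [
    "WardResult",
    "VectorClusterModel",
    "RepresentativeSeries",
    "TransitionGraph",
    "GraphClusterModel",
    "ward_cluster",
    "fit_phase1",
    "assign_vector",
    "representative_series",
    "build_graphs",
    "fit_phase2",
    "vector_model_to_dict",
    "vector_model_from_dict",
    "graphs_to_dict",
    "graphs_from_dict",
    "graph_model_to_dict",
    "graph_model_from_dict",
]


# --------------------------------------------------------------------------
# Ward agglomerative clustering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WardResult:
    """Outcome of agglomerative Ward clustering halted at K clusters.

    ``assignments`` are labels in ``1..K``, numbered by order of first
    appearance (the cluster containing the earliest input point is 1).
    ``merge_history`` rows are ``(id_a, id_b, height)`` with id_a < id_b.
    """

    K: int
    assignments: np.ndarray
    centroids: np.ndarray
    merge_history: tuple[tuple[int, int, float], ...]


def ward_cluster(points: np.ndarray, K: int) -> WardResult:
    """Agglomerative Ward clustering of row vectors, stopped at K clusters.

    At each step the pair of clusters whose merge least increases total
    within-cluster variance is merged; ties go to the lexicographically
    smallest id pair.  Raises if ``K`` exceeds the number of points.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be a 2-D array (m, d)")
    m = X.shape[0]
    if not 1 <= K <= m:
        raise ValueError(f"need 1 <= K <= {m}, got K={K}")

    # squared Ward distances between singletons are squared Euclidean;
    # full symmetric matrix with inactive slots masked to +inf
    sq = np.sum(X * X, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    D2[D2 < 0] = 0.0  # numerical noise on duplicates
    np.fill_diagonal(D2, np.inf)

    ids = np.arange(m)             # slot -> current cluster id
    sizes = np.ones(m)
    active = np.ones(m, dtype=bool)
    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    history: list[tuple[int, int, float]] = []
    row_min = D2.min(axis=1) if m > 1 else np.array([np.inf])

    for step in range(m - K):
        v = row_min[active].min()
        # exact ties resolve to the lexicographically smallest (id_a, id_b)
        # pair; both endpoints of any minimal pair are rows whose cached
        # min equals v, so the smallest-id such row is one endpoint
        cand = np.flatnonzero(active & (row_min == v))
        p = int(cand[np.argmin(ids[cand])])
        qs = np.flatnonzero(D2[p] == v)
        q = int(qs[np.argmin(ids[qs])])
        d2 = float(D2[p, q])
        a, b = sorted((int(ids[p]), int(ids[q])))
        history.append((a, b, float(np.sqrt(max(d2, 0.0)))))

        si, sj = sizes[p], sizes[q]
        # Lance–Williams (Ward) update of squared distances to all others
        sk = sizes
        d_new = ((si + sk) * D2[p] + (sj + sk) * D2[q] - sk * d2) / (si + sj + sk)
        d_new[~active] = np.inf
        d_new[[p, q]] = np.inf

        old_p = D2[p].copy()
        old_q = D2[q].copy()
        new_id = m + step
        members[new_id] = members.pop(int(ids[p])) + members.pop(int(ids[q]))
        ids[p] = new_id
        sizes[p] = si + sj
        active[q] = False
        D2[p, :] = d_new
        D2[:, p] = d_new
        D2[q, :] = np.inf
        D2[:, q] = np.inf
        row_min[q] = np.inf
        row_min[p] = d_new.min() if active.sum() > 1 else np.inf
        # a row's cached min is stale if it pointed at p or q, or if the
        # merged cluster moved closer
        others = active.copy()
        others[p] = False
        stale = others & ((row_min == old_p) | (row_min == old_q))
        if stale.any():
            row_min[stale] = D2[stale].min(axis=1)
        better = others & ~stale & (d_new < row_min)
        row_min[better] = d_new[better]

    # label clusters 1..K by order of first appearance in the input
    assignments = np.zeros(m, dtype=int)
    order = sorted(
        (int(i) for i in ids[active]), key=lambda cid: min(members[cid])
    )
    centroids = np.zeros((K, X.shape[1]))
    for label, cid in enumerate(order, start=1):
        assignments[members[cid]] = label
        centroids[label - 1] = X[members[cid]].mean(axis=0)
    return WardResult(K, assignments, centroids, tuple(history))


# --------------------------------------------------------------------------
# Phase 1: place-vector clustering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VectorClusterModel:
    """Fitted phase-1 Ward clustering of place vectors."""

    K1: int
    assignments: np.ndarray
    centroids: np.ndarray
    merge_history: tuple[tuple[int, int, float], ...]
    component_ids: tuple[str, ...] = ()


def fit_phase1(series: PlaceVectorSeries, K1: int = 8) -> VectorClusterModel:
    """Ward-cluster the place vectors into K1 spatial occupancy patterns."""
    X = series.matrix
    if X.shape[0] < K1:
        raise ValueError(f"need at least K1={K1} vectors, got {X.shape[0]}")
    res = ward_cluster(X, K1)
    return VectorClusterModel(
        K1, res.assignments, res.centroids, res.merge_history, series.component_ids
    )


def assign_vector(model: VectorClusterModel, v: np.ndarray) -> int:
    """Nearest-centroid label (1-based) for a new place vector; ties take
    the lowest label."""
    v = np.asarray(v, dtype=float)
    if v.shape != (model.centroids.shape[1],):
        raise ValueError(
            f"vector has dimension {v.shape}, model expects "
            f"({model.centroids.shape[1]},)"
        )
    d = np.linalg.norm(model.centroids - v, axis=1)
    return int(np.argmin(d)) + 1


def _assign_matrix(model: VectorClusterModel, X: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(X[:, None, :] - model.centroids[None, :, :], axis=2)
    return np.argmin(d, axis=1) + 1


# --------------------------------------------------------------------------
# Step 2: representative sub-interval series
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RepresentativeSeries:
    """Per outer interval, the n_sub majority phase-1 labels."""

    interval_length_s: float
    n_sub: int
    labels: np.ndarray          # (n_intervals, n_sub) int labels 1..K1
    start_time: float = 0.0

    @property
    def n_intervals(self) -> int:
        return self.labels.shape[0]

    def interval_start(self, i: int) -> float:
        return self.start_time + i * self.interval_length_s


def representative_series(
    model: VectorClusterModel,
    series: PlaceVectorSeries,
    interval_length_s: float = 200.0,
    n_sub: int = 10,
    labels: np.ndarray | None = None,
) -> RepresentativeSeries:
    """Segment the label series into intervals and pick per-sub-interval
    majority representatives.

    The cluster-occupancy function is piecewise constant: each vector window
    carries its phase-1 label.  Within every sub-interval the label with the
    largest total occupancy duration wins (ties: lowest label).  A
    sub-interval with no occupancy (gapped logs) inherits the previous
    representative, or the first vector's label if there is none.  The
    trailing partial interval is dropped.

    ``labels`` overrides per-vector labels (e.g. the fitted training
    assignments); by default vectors are assigned to the nearest centroid.
    """
    if interval_length_s <= 0 or n_sub < 1:
        raise ValueError("interval_length_s and n_sub must be positive")
    if labels is None:
        labels = _assign_matrix(model, series.matrix)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != len(series):
        raise ValueError("labels length must match series length")

    t0 = series.start_time
    span = (series.vectors[-1].window_end_s - t0) if len(series) else 0.0
    n_int = int(span / interval_length_s + 1e-9)
    if n_int < 1:
        warnings.warn("series shorter than one interval; empty result", stacklevel=2)
        return RepresentativeSeries(
            interval_length_s, n_sub, np.zeros((0, n_sub), dtype=int), t0
        )

    sub_len = interval_length_s / n_sub
    windows = [(v.window_start_s, v.window_end_s) for v in series.vectors]
    reps = np.zeros((n_int, n_sub), dtype=int)
    prev_rep = int(labels[0])
    for i in range(n_int):
        for k in range(n_sub):
            a = t0 + i * interval_length_s + k * sub_len
            b = a + sub_len
            occ: dict[int, float] = {}
            for (ws, we), lab in zip(windows, labels):
                ov = min(we, b) - max(ws, a)
                if ov > 0:
                    occ[int(lab)] = occ.get(int(lab), 0.0) + ov
            if occ:
                best = max(occ.items(), key=lambda kv: (kv[1], -kv[0]))[0]
                prev_rep = best
            reps[i, k] = prev_rep
    return RepresentativeSeries(interval_length_s, n_sub, reps, t0)


# --------------------------------------------------------------------------
# Step 2.3 / 3: transition graphs and their clustering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionGraph:
    """Edge-weighted directed graph over phase-1 labels for one interval.

    ``adjacency[i, j]`` counts sub-interval transitions from label ``i+1``
    to label ``j+1``; entries always sum to ``n_sub``.
    """

    interval_index: int
    adjacency: np.ndarray
    start_time: float = 0.0

    @property
    def total_weight(self) -> int:
        return int(self.adjacency.sum())

    def to_networkx(self):
        """Optional export as a networkx.DiGraph with 1-based node labels."""
        import networkx as nx

        g = nx.DiGraph()
        K = self.adjacency.shape[0]
        for i in range(K):
            for j in range(K):
                w = int(self.adjacency[i, j])
                if w:
                    g.add_edge(i + 1, j + 1, weight=w)
        return g


def build_graphs(rep: RepresentativeSeries, K1: int) -> list[TransitionGraph]:
    """One transition graph per outer interval.

    For interval i and sub-interval step k = 1..n, edge
    ``(C_i^k, C_i^{k+1})`` gains one unit, where ``C_i^{n+1}`` is the first
    representative of interval i+1; the final interval's last step is a
    self-loop on its own last representative (there is no next interval).
    Graphs live on the fixed 1..K1 label universe so their adjacency
    matrices are mutually comparable.
    """
    labels = rep.labels
    if labels.size == 0:
        raise ValueError("empty representative series")
    if labels.min() < 1 or labels.max() > K1:
        raise ValueError("representative labels outside 1..K1")
    n_int, n_sub = labels.shape
    graphs = []
    for i in range(n_int):
        A = np.zeros((K1, K1), dtype=int)
        for k in range(n_sub):
            src = labels[i, k]
            if k + 1 < n_sub:
                dst = labels[i, k + 1]
            elif i + 1 < n_int:
                dst = labels[i + 1, 0]
            else:
                dst = labels[i, k]
            A[src - 1, dst - 1] += 1
        graphs.append(TransitionGraph(i, A, rep.interval_start(i)))
    return graphs


@dataclass(frozen=True)
class GraphClusterModel:
    """Fitted phase-2 Ward clustering of transition-graph adjacency matrices.

    ``distance_stats`` caches, per cluster label, the mean and standard
    deviation of member distances to the cluster centroid (Frobenius);
    anomaly scoring thresholds on them.
    """

    K2: int
    assignments: np.ndarray
    centroid_matrices: np.ndarray        # (K2, K1, K1)
    merge_history: tuple[tuple[int, int, float], ...]
    distance_stats: tuple[tuple[float, float], ...] = ()


def fit_phase2(graphs: list[TransitionGraph], K2: int = 5) -> GraphClusterModel:
    """Ward-cluster adjacency matrices (flattened row-major, Euclidean)."""
    if not graphs:
        raise ValueError("no graphs to cluster")
    shape = graphs[0].adjacency.shape
    if any(g.adjacency.shape != shape for g in graphs):
        raise ValueError("heterogeneous adjacency shapes")
    if len(graphs) < K2:
        raise ValueError(f"need at least K2={K2} graphs, got {len(graphs)}")
    X = np.stack([g.adjacency.reshape(-1) for g in graphs]).astype(float)
    res = ward_cluster(X, K2)
    centroids = res.centroids.reshape(K2, *shape)
    stats = []
    for label in range(1, K2 + 1):
        member = X[res.assignments == label]
        d = np.linalg.norm(member - res.centroids[label - 1], axis=1)
        stats.append((float(d.mean()), float(d.std())))
    return GraphClusterModel(
        K2, res.assignments, centroids, res.merge_history, tuple(stats)
    )


# --------------------------------------------------------------------------
# JSON (de)serialization — CLI stage hand-off
# --------------------------------------------------------------------------

def vector_model_to_dict(model: VectorClusterModel) -> dict:
    return {
        "k1": model.K1,
        "assignments": model.assignments.tolist(),
        "centroids": model.centroids.tolist(),
        "merge_history": [list(m) for m in model.merge_history],
        "component_ids": list(model.component_ids),
    }


def vector_model_from_dict(doc: dict) -> VectorClusterModel:
    return VectorClusterModel(
        K1=int(doc["k1"]),
        assignments=np.asarray(doc["assignments"], dtype=int),
        centroids=np.asarray(doc["centroids"], dtype=float),
        merge_history=tuple((int(a), int(b), float(d)) for a, b, d in doc["merge_history"]),
        component_ids=tuple(doc.get("component_ids", ())),
    )


def graphs_to_dict(graphs: list[TransitionGraph]) -> dict:
    return {
        "graphs": [
            {
                "interval_index": g.interval_index,
                "start_time": g.start_time,
                "adjacency": [int(x) for x in g.adjacency.reshape(-1)],
                "k": int(g.adjacency.shape[0]),
            }
            for g in graphs
        ]
    }


def graphs_from_dict(doc: dict) -> list[TransitionGraph]:
    out = []
    for g in doc["graphs"]:
        k = int(g["k"])
        adj = np.asarray(g["adjacency"], dtype=int).reshape(k, k)
        out.append(TransitionGraph(int(g["interval_index"]), adj, float(g["start_time"])))
    return out


def graph_model_to_dict(model: GraphClusterModel) -> dict:
    return {
        "k2": model.K2,
        "assignments": model.assignments.tolist(),
        "centroid_matrices": model.centroid_matrices.tolist(),
        "merge_history": [list(m) for m in model.merge_history],
        "distance_stats": [list(s) for s in model.distance_stats],
    }


def graph_model_from_dict(doc: dict) -> GraphClusterModel:
    return GraphClusterModel(
        K2=int(doc["k2"]),
        assignments=np.asarray(doc["assignments"], dtype=int),
        centroid_matrices=np.asarray(doc["centroid_matrices"], dtype=float),
        merge_history=tuple((int(a), int(b), float(d)) for a, b, d in doc["merge_history"]),
        distance_stats=tuple((float(m), float(s)) for m, s in doc["distance_stats"]),
    )
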