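"""Pairwise dissimilarities, the penalized reciprocal k-NN graph, and
geodesic distances.

The geodesic metric used throughout the pipeline is the shortest-path
length on a *penalized reciprocal k-NN graph* (PRKNNG): points are linked
only when each is among the other's k nearest neighbors (reciprocity damps
the influence of outliers), and the possibly disconnected result is
repaired by greedily bridging components at their closest pair with an
exponentially penalized weight, so that shortcuts across genuinely distant
clusters stay expensive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform

from .data import DataMatrix

__all__ = [
    "DistanceMatrix",
    "NeighborGraph",
    "DIRECT_METRICS",
    "pairwise_distance",
    "build_prknng",
    "geodesic_distances",
    "exponential_bridge_penalty",
]

#: The five direct (non-geodesic) metrics.  "correlation" is 1 - Pearson r;
#: note it does NOT satisfy the triangle inequality in this form.
DIRECT_METRICS = ("euclidean", "cityblock", "chebychev", "cosine", "correlation")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative ``N x N`` dissimilarity matrix.

    The triangle inequality holds for euclidean/cityblock/chebychev and for
    geodesic output (a path metric), but NOT for the correlation variant
    (1 - Pearson r), which is kept in that form deliberately because of its
    ubiquity in functional-connectivity work.
    """

    values: np.ndarray
    metric_name: str
    base_metric: str | None = None  # underlying metric when geodesic
    k: int | None = None            # neighbor count when geodesic

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        header = f"# metric={self.metric_name}"
        if self.base_metric:
            header += f" base={self.base_metric} k={self.k}"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, self.values, delimiter="\t")


@dataclass
class NeighborGraph:
    """Weighted undirected reciprocal k-NN graph with flagged bridges.

    ``edges`` maps unordered index pairs ``(i, j)`` with ``i < j`` to a
    positive weight; ``bridge_flags`` is the subset of pairs added by the
    connectivity repair (their weights carry the exponential penalty).
    """

    n_points: int
    edges: dict[tuple[int, int], float]
    bridge_flags: set[tuple[int, int]] = field(default_factory=set)
    k: int = 1
    base_metric: str = "euclidean"

    def adjacency(self) -> csr_matrix:
        if not self.edges:
            return csr_matrix((self.n_points, self.n_points))
        ij = np.array(list(self.edges.keys()))
        w = np.fromiter(self.edges.values(), dtype=float, count=len(self.edges))
        rows = np.concatenate([ij[:, 0], ij[:, 1]])
        cols = np.concatenate([ij[:, 1], ij[:, 0]])
        return csr_matrix((np.concatenate([w, w]), (rows, cols)),
                          shape=(self.n_points, self.n_points))

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(self.adjacency(), directed=False)
        return ncomp == 1


def pairwise_distance(data: DataMatrix, metric: str) -> DistanceMatrix:
    """All-pairs dissimilarity between the rows of ``data``.

    ``metric`` is one of ``euclidean``, ``cityblock``, ``chebychev``,
    ``cosine``, ``correlation``.  Correlation is 1 - Pearson correlation;
    rows with zero variance make it undefined and raise.

    Raises
    ------
    ValueError
        On an unknown metric, a zero-variance row under correlation, or a
        zero-norm row under cosine, naming the offending row.
    """
    if metric not in DIRECT_METRICS:
        raise ValueError(f"unknown metric {metric!r}; pick one of {DIRECT_METRICS}")
    X = data.values
    if metric == "correlation":
        sd = X.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"correlation distance undefined: row {bad[0]} has zero variance")
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(
                f"cosine distance undefined: row {bad[0]} is the zero vector")
    scipy_name = {"chebychev": "chebyshev"}.get(metric, metric)
    D = squareform(pdist(X, metric=scipy_name))
    # pdist can leave tiny negative fuzz on the angle metrics
    np.clip(D, 0.0, None, out=D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, metric_name=metric)


def exponential_bridge_penalty(d: float, mean_edge_weight: float) -> float:
    """Penalized weight for a repair bridge: ``d * exp(d / d_bar)``.

    ``d`` is the raw inter-component distance and ``d_bar`` the mean weight
    of the reciprocal edges already in the graph, making the penalty
    scale-free.  Falls back to the raw distance when the graph has no
    reciprocal edges (then no scale exists).
    """
    if mean_edge_weight <= 0:
        return d
    # cap the exponent so extreme gaps stay finite (ordering is preserved:
    # beyond the cap the raw distance still ranks the bridges)
    return float(d * np.exp(min(d / mean_edge_weight, 500.0)))


def build_prknng(dist: DistanceMatrix, k: int,
                 penalty: Callable[[float, float], float] = exponential_bridge_penalty,
                 ) -> NeighborGraph:
    """Build the penalized reciprocal k-NN graph from a direct metric.

    An edge ``(i, j)`` is reciprocal when j is among the k nearest
    neighbors of i AND i among the k nearest of j (ties in distance broken
    by lower index, so the construction is deterministic).  If the
    reciprocal graph is disconnected, components are merged greedily: the
    globally closest inter-component pair is bridged with weight
    ``penalty(d, mean reciprocal edge weight)`` until one component
    remains; bridges are flagged.
    """
    n = dist.n
    if n < 2:
        raise ValueError("need at least 2 points")
    if k >= n:
        raise ValueError(f"k={k} must be < number of points n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = dist.values
    # argsort of (distance, index) pairs excluding self; lexsort on index
    # second realizes the lower-index tie-break.
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), D), axis=1)
    knn: list[set[int]] = []
    for i in range(n):
        row = [j for j in order[i] if j != i][:k]
        knn.append(set(row))
    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in knn[i]:
            if i < j and i in knn[j]:
                edges[(i, j)] = float(D[i, j])
    graph = NeighborGraph(n_points=n, edges=edges, k=k,
                          base_metric=dist.metric_name)
    # connectivity repair
    mean_w = float(np.mean(list(edges.values()))) if edges else 0.0
    while True:
        ncomp, labels = connected_components(graph.adjacency(), directed=False)
        if ncomp == 1:
            break
        cross = labels[:, None] != labels[None, :]
        Dm = np.where(cross, D, np.inf)
        flat = int(np.argmin(Dm))  # row-major argmin = lowest-index tie-break
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        d = float(D[i, j])
        graph.edges[(i, j)] = penalty(d, mean_w)
        graph.bridge_flags.add((i, j))
    return graph


def geodesic_distances(graph: NeighborGraph, mode: str = "weighted") -> DistanceMatrix:
    """All-pairs shortest-path lengths on the neighbor graph.

    ``weighted`` (default) sums edge weights, matching the geodesic
    dissimilarity definition; ``hops`` counts edges, as when the graph
    itself is read as the lens.
    """
    if mode not in ("weighted", "hops"):
        raise ValueError("mode must be 'weighted' or 'hops'")
    adj = graph.adjacency()
    G = shortest_path(adj, method="D", directed=False,
                      unweighted=(mode == "hops"))
    if not np.all(np.isfinite(G)):
        raise AssertionError("neighbor graph is disconnected; repair failed")
    G = (G + G.T) / 2.0
    np.fill_diagonal(G, 0.0)
    return DistanceMatrix(G, metric_name="geodesic",
                          base_metric=graph.base_metric, k=graph.k)
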