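"""Shape-graph assembly and the temporal similarity summaries derived
from it.

Nodes are the partial clusters; an undirected edge joins two nodes exactly
when they share at least one time point (the overlap of the cover is what
makes sharing possible).  From the graph we derive the temporal
connectivity matrix — time points are similar when they co-occur in a node
or in adjacent nodes — and its row summary, the normalized degree, whose
abrupt changes mark state transitions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .partial_clustering import ClusterSet

__all__ = ["ShapeGraph", "TCM", "build_shape_graph", "compute_tcm",
           "normalized_degree"]


@dataclass
class ShapeGraph:
    """Nodes = clusters of time-point indices; edges = shared members."""

    nodes: list[dict]                 # {"id", "members", "bin_id", "method"}
    edges: set[tuple[int, int]]       # unordered node-id pairs, id_a < id_b
    n_points: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def members(self, node_id: int) -> np.ndarray:
        return self.nodes[node_id]["members"]

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for node in self.nodes:
            G.add_node(node["id"], size=len(node["members"]),
                       members=",".join(map(str, node["members"])),
                       bin_id=node["bin_id"])
        G.add_edges_from(self.edges)
        return G

    def covered_points(self) -> np.ndarray:
        if not self.nodes:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([n["members"] for n in self.nodes]))

    def largest_component(self) -> list[int]:
        """Node ids of the largest connected component (ties: the one
        containing the smallest node id)."""
        G = self.to_networkx()
        if G.number_of_nodes() == 0:
            return []
        comps = sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c)))
        return sorted(comps[0])

    # -- persistence ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_points": self.n_points,
            "nodes": [{"id": n["id"], "bin_id": n["bin_id"],
                       "members": [int(i) for i in n["members"]]}
                      for n in self.nodes],
            "edges": sorted([list(e) for e in self.edges]),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShapeGraph":
        doc = json.loads(Path(path).read_text())
        nodes = [{"id": n["id"], "bin_id": n.get("bin_id", -1),
                  "members": np.array(n["members"], dtype=int),
                  "method": n.get("method", "")} for n in doc["nodes"]]
        edges = {tuple(sorted(e)) for e in doc["edges"]}
        return cls(nodes=nodes, edges=edges, n_points=doc["n_points"])

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def membership_frame(self) -> pd.DataFrame:
        """Long-format (time point, node id) membership table."""
        rows = [(int(t), n["id"]) for n in self.nodes for t in n["members"]]
        return pd.DataFrame(rows, columns=["timepoint", "node_id"])


@dataclass
class TCM:
    """Binary N x N temporal connectivity matrix."""

    values: np.ndarray
    rule: str = "same-node-or-adjacent"

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_shape_graph(clusters: ClusterSet, n_points: int | None = None) -> ShapeGraph:
    """One node per cluster; edge between nodes iff members intersect.

    Clusters must come from a single cover.  Self-loops are never created.
    """
    n_points = clusters.n_points if n_points is None else n_points
    nodes = []
    for i, c in enumerate(clusters.clusters):
        if c.members.size == 0:
            continue
        nodes.append({"id": len(nodes), "members": np.sort(c.members),
                      "bin_id": c.bin_id, "method": c.method})
    # membership matrix (nodes x points) gives the pairwise intersection
    # counts in one product
    k = len(nodes)
    edges: set[tuple[int, int]] = set()
    if k > 1:
        # float matmul so BLAS does the pairwise intersection counts
        M = np.zeros((k, n_points), dtype=np.float32)
        for node in nodes:
            M[node["id"], node["members"]] = 1.0
        inter = (M @ M.T) > 0.5
        a, b = np.nonzero(np.triu(inter, 1))
        edges = set(zip(a.tolist(), b.tolist()))
    return ShapeGraph(nodes=nodes, edges=edges, n_points=n_points)


def compute_tcm(graph: ShapeGraph) -> TCM:
    """TCM[i, j] = 1 iff i and j sit in the same node or in adjacent nodes.

    The diagonal is 1 for every covered point; rows of uncovered points are
    all zero.
    """
    n = graph.n_points
    k = graph.n_nodes
    T = np.zeros((n, n), dtype=np.int8)
    if k == 0:
        return TCM(values=T)
    M = np.zeros((k, n), dtype=np.float32)
    for node in graph.nodes:
        M[node["id"], node["members"]] = 1.0
    # node adjacency including self: same node OR connected by an edge
    A = np.eye(k, dtype=np.float32)
    for a, b in graph.edges:
        A[a, b] = A[b, a] = 1.0
    T = ((M.T @ (A @ M)) > 0.5).astype(np.int8)
    return TCM(values=T)


def normalized_degree(tcm: TCM) -> np.ndarray:
    """Mean off-diagonal TCM row, min-max scaled to [0, 1].

    A constant raw series (e.g., the all-ones TCM of a single clique) maps
    to all-zeros with a warning.
    """
    n = tcm.n
    if n < 2:
        raise ValueError("need at least 2 time points")
    V = tcm.values.astype(float)
    raw = (V.sum(axis=1) - np.diag(V)) / (n - 1)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn("normalized degree is constant; returning zeros")
        return np.zeros(n)
    return (raw - lo) / (hi - lo)
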