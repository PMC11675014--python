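"""Per-bin clustering in the ORIGINAL high-dimensional metric.

The nodes of the shape graph are clusters of each bin's members, computed
on the original-space distance matrix — lens coordinates never enter this
stage.  Two modes are provided: single linkage with the classic
histogram-gap cutoff, and density-based clustering (DBSCAN semantics,
noise dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import DBSCAN

from .binning import BinCover
from .distances import DistanceMatrix

__all__ = ["Cluster", "ClusterSet", "cluster_bin_linkage", "cluster_bin_density",
           "cluster_cover"]


@dataclass
class Cluster:
    members: np.ndarray          # sorted time-point indices
    bin_id: int
    method: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class ClusterSet:
    """Per-bin clusters; linkage mode partitions each bin, density mode may
    drop noise points (union of clusters is a subset of the bin)."""

    clusters: list[Cluster]
    n_points: int

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_bin_linkage(members: np.ndarray, dist: DistanceMatrix,
                        hist_bins: int = 10) -> list[np.ndarray]:
    """Single-linkage clusters of ``members`` with the histogram-gap cut.

    The merge heights of the single-linkage dendrogram (original-space
    distances) are histogrammed into ``hist_bins`` equal-width bins over
    ``[0, max height]``; the cut threshold is the left edge of the first
    empty histogram bin that follows a nonempty one (a gap below the
    smallest merge separates nothing).  No such gap means one cluster.
    """
    if hist_bins < 2:
        raise ValueError("hist_bins must be >= 2")
    members = np.sort(np.asarray(members, dtype=int))
    m = members.size
    if m == 0:
        return []
    if m == 1:
        return [members.copy()]
    sub = dist.values[np.ix_(members, members)]
    Z = linkage(squareform(sub, checks=False), method="single")
    heights = Z[:, 2]
    hmax = heights.max()
    if hmax == 0:  # all members identical
        return [members.copy()]
    counts, edges = np.histogram(heights, bins=hist_bins, range=(0.0, hmax))
    # the gap must SEPARATE small merges from large ones: leading empty
    # bins (no merge that short) are not a gap, so skip to the first empty
    # bin after a nonempty one
    nonempty = np.flatnonzero(counts > 0)
    empty = np.flatnonzero((counts == 0) & (np.arange(hist_bins) > nonempty[0]))
    if empty.size == 0:
        return [members.copy()]
    cut = edges[empty[0]]
    flat = fcluster(Z, t=cut, criterion="distance")
    return [members[flat == c] for c in np.unique(flat)]


def cluster_bin_density(members: np.ndarray, dist: DistanceMatrix,
                        eps: float, min_pts: int = 3) -> list[np.ndarray]:
    """Density-based clusters of ``members``; noise points are dropped.

    A core point has at least ``min_pts`` members (itself included) within
    ``eps`` in the original metric; clusters are the connected components
    of density reachability.  Members are processed in sorted index order,
    so border points attach to the first cluster discovered in index order
    and the result is independent of input ordering.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    members = np.sort(np.asarray(members, dtype=int))
    m = members.size
    if m == 0:
        return []
    sub = dist.values[np.ix_(members, members)]
    labels = DBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(sub).labels_
    return [members[labels == c] for c in np.unique(labels) if c != -1]


def cluster_cover(cover: BinCover, dist: DistanceMatrix, method: str = "linkage",
                  hist_bins: int = 10, eps: float | None = None,
                  min_pts: int = 3) -> ClusterSet:
    """Cluster every bin of a cover; the resulting ClusterSet feeds the
    shape-graph assembly."""
    clusters: list[Cluster] = []
    for bin_id, members in enumerate(cover.bins):
        if method == "linkage":
            parts = cluster_bin_linkage(members, dist, hist_bins=hist_bins)
            params = {"hist_bins": hist_bins}
        elif method in ("dbscan", "density"):
            if eps is None:
                raise ValueError("density clustering requires eps")
            parts = cluster_bin_density(members, dist, eps=eps, min_pts=min_pts)
            params = {"eps": eps, "min_pts": min_pts}
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        for part in parts:
            clusters.append(Cluster(members=part, bin_id=bin_id,
                                    method=method, params=params))
    return ClusterSet(clusters=clusters, n_points=cover.n_points)
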