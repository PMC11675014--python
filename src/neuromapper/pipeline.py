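"""Five-stage Mapper pipeline glued end to end for a single configuration.

Stages: (1) pairwise distances (optionally geodesic on the penalized
reciprocal k-NN graph), (2) lens (extrinsic embedding or the intrinsic
graph lens), (3) overlapping cover, (4) partial clustering in the
original metric, (5) shape-graph assembly.  :func:`evaluate_result`
attaches the validation report and goodness-of-fit metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .binning import BinCover, extrinsic_bins, intrinsic_bins
from .data import DataMatrix
from .distances import (DistanceMatrix, NeighborGraph, build_prknng,
                        geodesic_distances, pairwise_distance)
from .evaluation import (GOFResult, ValidationReport, average_delay,
                         circleness, detect_transitions, validate)
from .lenses import Lens, embed_cmds, embed_delegate, intrinsic_lens
from .partial_clustering import cluster_cover
from .shapegraph import ShapeGraph, build_shape_graph, compute_tcm, normalized_degree
from .synthdata import StateLabels

__all__ = ["MapperConfig", "MapperResult", "run_mapper", "evaluate_result"]


@dataclass
class MapperConfig:
    """One fully specified Mapper run (no list-valued fields)."""

    metric: str = "euclidean"          # base dissimilarity
    geodesic: bool = True              # route through the PRKNNG
    k: int = 12                        # neighbor count for the PRKNNG
    lens_algorithm: str = "CMDS"       # or "intrinsic"
    lens_dim: int = 2
    lens_params: dict[str, Any] = field(default_factory=dict)
    bin_kind: str = "extrinsic"        # "extrinsic" | "intrinsic"
    resolution: int = 20
    gain: float = 70.0
    sides: int = 4                     # rectangle cover only
    cluster_method: str = "linkage"    # "linkage" | "dbscan"
    hist_bins: int = 10
    eps: float | None = None
    min_pts: int = 3
    preprocess: str = "none"           # "none" | "zscore"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sides != 4:
            raise ValueError(
                "only axis-aligned rectangles (sides=4) are supported; "
                f"got sides={self.sides}")
        if self.bin_kind == "intrinsic" and self.lens_algorithm != "intrinsic":
            raise ValueError("intrinsic binning requires the intrinsic lens")
        if self.lens_algorithm == "intrinsic" and self.bin_kind != "intrinsic":
            raise ValueError("the intrinsic lens requires intrinsic binning")
        if self.lens_algorithm == "intrinsic" and not self.geodesic:
            raise ValueError("the intrinsic lens is built on the k-NN graph; "
                             "set geodesic=True")

    def to_dict(self) -> dict[str, Any]:
        return {
            "metric": self.metric, "geodesic": self.geodesic, "k": self.k,
            "lens_algorithm": self.lens_algorithm, "lens_dim": self.lens_dim,
            "lens_params": dict(self.lens_params), "bin_kind": self.bin_kind,
            "resolution": self.resolution, "gain": self.gain,
            "sides": self.sides, "cluster_method": self.cluster_method,
            "hist_bins": self.hist_bins, "eps": self.eps,
            "min_pts": self.min_pts, "preprocess": self.preprocess,
            "seed": self.seed,
        }


@dataclass
class MapperResult:
    config: MapperConfig
    graph: ShapeGraph
    lens: Lens
    cover: BinCover
    dist: DistanceMatrix            # metric-stage output (geodesic if used)
    base_dist: DistanceMatrix       # the direct-metric distances
    knn_graph: NeighborGraph | None
    validation: ValidationReport | None = None
    gof: GOFResult | None = None


def run_mapper(data: DataMatrix, config: MapperConfig,
               precomputed: dict | None = None) -> MapperResult:
    """Execute the five stages for one configuration.

    ``precomputed`` may carry reusable stage outputs keyed by
    ``"base_dist"``, ``"knn_graph"``, ``"dist"``, ``"lens"`` — handy when
    sweeping resolution and gain, which only affect the cover onward.
    """
    pre = precomputed or {}
    if config.preprocess == "zscore":
        data = data.zscore() if "zscored" not in pre else pre["zscored"]
    elif config.preprocess != "none":
        raise ValueError(f"unknown preprocess {config.preprocess!r}")

    base_dist = pre.get("base_dist") or pairwise_distance(data, config.metric)
    knn_graph = pre.get("knn_graph")
    if config.geodesic and knn_graph is None:
        knn_graph = build_prknng(base_dist, k=config.k)
    dist = pre.get("dist")
    if dist is None:
        dist = geodesic_distances(knn_graph) if config.geodesic else base_dist

    lens = pre.get("lens")
    if lens is None:
        if config.lens_algorithm == "intrinsic":
            lens = intrinsic_lens(knn_graph)
            # reuse the geodesic matrix already computed for the metric stage
            lens.geo = dist
        elif config.lens_algorithm == "CMDS":
            lens = embed_cmds(dist, d=config.lens_dim)
        else:
            from .lenses import EMBEDDING_REGISTRY
            form = EMBEDDING_REGISTRY.get(config.lens_algorithm, ("distances",))[0]
            source = dist if form == "distances" else data
            lens = embed_delegate(source, config.lens_algorithm,
                                  d=config.lens_dim, params=config.lens_params,
                                  seed=config.seed)

    if config.bin_kind == "extrinsic":
        cover = extrinsic_bins(lens, R=config.resolution, g=config.gain)
    else:
        cover = intrinsic_bins(lens, R=config.resolution, g=config.gain)

    clusters = cluster_cover(cover, dist, method=config.cluster_method,
                             hist_bins=config.hist_bins, eps=config.eps,
                             min_pts=config.min_pts)
    graph = build_shape_graph(clusters)
    return MapperResult(config=config, graph=graph, lens=lens, cover=cover,
                        dist=dist, base_dist=base_dist, knn_graph=knn_graph)


def evaluate_result(result: MapperResult, data: DataMatrix,
                    schedule: StateLabels | None = None,
                    expected_transitions: np.ndarray | None = None,
                    n_change: int | None = None,
                    tau: float = 11.0, delta: float = 12.0) -> MapperResult:
    """Attach validation and goodness-of-fit to a Mapper result.

    Circleness is computed when the data carry the four-state simulated
    labels; transition extraction runs when expected transition times are
    supplied (directly or via ``schedule``).
    """
    result.validation = validate(result.graph, tr=data.tr, tau=tau)
    gof = GOFResult(delta=delta)
    labels = data.labels
    if labels is not None and set(np.unique(labels)) <= {
            "stable-low", "transition-up", "stable-high", "transition-down"}:
        gof.circleness = circleness(result.graph, labels)
    if expected_transitions is None and schedule is not None:
        expected_transitions = schedule.interior_boundaries()
    if expected_transitions is not None:
        expected = list(np.asarray(expected_transitions, dtype=float))
        if n_change is None:
            n_change = len(expected)
        tcm = compute_tcm(result.graph)
        deg = normalized_degree(tcm)
        try:
            gof.transitions = detect_transitions(deg, n_change=n_change,
                                                 tr=data.tr)
        except ValueError:   # constant degree: nothing detectable
            gof.transitions = []
        gof.average_delay = average_delay(gof.transitions, expected)
        gof.passed = gof.average_delay <= gof.delta
    result.gof = gof
    return result
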