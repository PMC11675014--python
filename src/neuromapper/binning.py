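"""Overlapping covers of the lens.

Extrinsic covers tile each embedding dimension with ``R`` equal intervals
whose width is inflated so adjacent intervals overlap by exactly ``g``
percent of their width; bins are the Cartesian products of intervals.
Intrinsic covers pick ``R`` landmarks on the k-NN graph by farthest-point
sampling on geodesic distances and collect, per landmark, every point
within ``4 * epsilon * g / 100`` of it (``2 * epsilon`` = minimum pairwise
landmark distance).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .lenses import Lens

__all__ = ["BinCover", "extrinsic_bins", "intrinsic_bins", "farthest_point_sampling"]


@dataclass
class BinCover:
    """Ordered list of overlapping time-point index sets.

    ``descriptors`` records per-bin provenance: rectangle bounds for the
    extrinsic cover, ``(landmark, radius, epsilon)`` for the intrinsic one.
    Empty bins are kept so that bin indexing is a pure function of (R, g).
    """

    bins: list[np.ndarray]
    descriptors: list[Any]
    resolution: int
    gain: float
    kind: str  # "extrinsic" | "intrinsic"
    n_points: int
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def covered_points(self) -> np.ndarray:
        if not self.bins:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([b for b in self.bins] or [[]]))

    def n_uncovered(self) -> int:
        return self.n_points - self.covered_points().size


def _axis_intervals(lo: float, hi: float, R: int, g: float):
    """R intervals whose centers tile [lo, hi] at spacing (hi-lo)/R, each of
    width spacing/(1 - g/100); returns (lows, highs) arrays."""
    span = hi - lo
    if span == 0:
        warnings.warn("degenerate lens dimension (zero range); using one "
                      "full-width interval")
        return np.full(R, lo - 0.5), np.full(R, lo + 0.5)
    s = span / R
    centers = lo + (np.arange(R) + 0.5) * s
    w = s / (1.0 - g / 100.0)
    return centers - w / 2, centers + w / 2


def extrinsic_bins(lens: Lens, R: int, g: float) -> BinCover:
    """Rectangle cover of an extrinsic lens: ``R^d`` overlapping bins.

    Membership intervals are half-open ``[lo, hi)`` except the last
    interval per dimension, which is right-closed so the maximum point is
    always covered.  Requires ``0 < g < 100``.
    """
    if lens.kind != "extrinsic":
        raise ValueError("extrinsic binning needs an extrinsic lens")
    if R < 1:
        raise ValueError("resolution must be >= 1")
    if not (0 < g < 100):
        raise ValueError(f"gain must be in (0, 100), got {g}")
    X = lens.coords
    n, d = X.shape
    axes = []
    for dim in range(d):
        lows, highs = _axis_intervals(X[:, dim].min(), X[:, dim].max(), R, g)
        # member mask per interval; last interval right-closed
        masks = []
        for r in range(R):
            m = (X[:, dim] >= lows[r]) & (
                (X[:, dim] <= highs[r]) if r == R - 1 else (X[:, dim] < highs[r]))
            masks.append(m)
        axes.append((lows, highs, masks))
    bins: list[np.ndarray] = []
    descriptors = []
    for combo in itertools.product(range(R), repeat=d):
        mask = np.ones(n, dtype=bool)
        bounds = []
        for dim, r in enumerate(combo):
            lows, highs, masks = axes[dim]
            mask &= masks[r]
            bounds.append((float(lows[r]), float(highs[r])))
        bins.append(np.flatnonzero(mask))
        descriptors.append(tuple(bounds))
    return BinCover(bins=bins, descriptors=descriptors, resolution=R, gain=g,
                    kind="extrinsic", n_points=n,
                    meta={"convention": "centers tile range at spacing range/R; "
                                        "width = spacing/(1-g/100)"})


def farthest_point_sampling(D: np.ndarray, R: int, start: int = 0) -> list[int]:
    """Pick R landmark indices maximizing minimum pairwise distance greedily.

    Starts from ``start``; each next landmark is the point farthest from
    the current landmark set (ties broken by lowest index).
    """
    n = D.shape[0]
    if not (0 <= start < n):
        raise ValueError("start index out of range")
    landmarks = [start]
    mind = D[start].copy()
    for _ in range(R - 1):
        nxt = int(np.argmax(mind))  # argmax takes the first (lowest) index on ties
        landmarks.append(nxt)
        mind = np.minimum(mind, D[nxt])
    return landmarks


def intrinsic_bins(lens: Lens, R: int, g: float, start: int | None = None,
                   rng: np.random.Generator | None = None) -> BinCover:
    """Landmark-ball cover of an intrinsic lens.

    Landmarks come from farthest-point sampling on the lens geodesic
    distances (deterministic start at index 0 unless ``start`` is given or
    a seeded ``rng`` supplies a random one).  With ``2*epsilon`` the
    minimum pairwise landmark distance, the bin of landmark ``x`` contains
    every point within geodesic distance ``4*epsilon*g/100`` of ``x``.
    Coverage is NOT guaranteed for small gains; uncovered points are
    counted in the cover and lower the coverage criterion downstream.
    """
    if lens.kind != "intrinsic":
        raise ValueError("intrinsic binning needs an intrinsic lens")
    D = lens.geo.values
    n = D.shape[0]
    if R > n:
        raise ValueError(f"landmark count R={R} exceeds number of points {n}")
    if R < 2:
        raise ValueError("need at least 2 landmarks")
    if not (0 < g <= 100):
        raise ValueError(f"gain must be in (0, 100], got {g}")
    if start is None:
        start = int(rng.integers(n)) if rng is not None else 0
    landmarks = farthest_point_sampling(D, R, start=start)
    L = np.array(landmarks)
    pair = D[np.ix_(L, L)]
    iu = np.triu_indices(R, 1)
    eps = float(pair[iu].min()) / 2.0
    radius = 4.0 * eps * g / 100.0
    bins = [np.flatnonzero(D[l] <= radius) for l in landmarks]
    descriptors = [(int(l), radius, eps) for l in landmarks]
    return BinCover(bins=bins, descriptors=descriptors, resolution=R, gain=g,
                    kind="intrinsic", n_points=n,
                    meta={"start": start, "epsilon": eps, "radius": radius})
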