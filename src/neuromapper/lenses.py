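"""Lens construction: extrinsic embeddings and the intrinsic graph lens.

The *lens* is the reduced representation that the cover is built on.  An
extrinsic lens is an ``N x d`` embedding (classical MDS implemented
natively; a registry delegates the other standard reducers to established
backends).  An intrinsic lens skips embedding entirely: it is the
penalized reciprocal k-NN graph together with its geodesic distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np

from .data import DataMatrix
from .distances import DistanceMatrix, NeighborGraph, geodesic_distances

__all__ = ["Lens", "embed_cmds", "embed_delegate", "intrinsic_lens",
           "EMBEDDING_REGISTRY", "registry_names"]


@dataclass
class Lens:
    """Either an N x d coordinate matrix (extrinsic) or a graph (intrinsic).

    Exactly one of ``coords`` / ``graph`` is populated.
    """

    kind: str  # "extrinsic" | "intrinsic"
    algorithm: str
    coords: np.ndarray | None = None
    graph: NeighborGraph | None = None
    geo: DistanceMatrix | None = None
    params: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == "extrinsic":
            if self.coords is None or self.graph is not None:
                raise ValueError("extrinsic lens must carry coords only")
            self.coords = np.asarray(self.coords, dtype=float)
            if not np.all(np.isfinite(self.coords)):
                raise ValueError("lens coords contain non-finite values")
        elif self.kind == "intrinsic":
            if self.graph is None or self.coords is not None:
                raise ValueError("intrinsic lens must carry a graph only")
        else:
            raise ValueError(f"unknown lens kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.coords.shape[0] if self.coords is not None else self.graph.n_points

    @property
    def d(self) -> int:
        if self.coords is None:
            raise ValueError("intrinsic lens has no embedding dimension")
        return self.coords.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        if self.coords is None:
            raise ValueError("intrinsic lens has no coordinates to persist")
        np.savetxt(path, self.coords, delimiter="\t")


def embed_cmds(dist: DistanceMatrix, d: int = 2) -> Lens:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers ``-1/2 J D^2 J`` and takes the top-``d`` spectral axes
    scaled by the square root of the eigenvalue.  A negative eigenvalue
    among the top d (distance matrix not Euclidean-realizable in d dims)
    zero-fills that axis and records a warning on the lens.
    """
    n = dist.n
    if d < 1:
        raise ValueError("d must be >= 1")
    if d >= n:
        raise ValueError(f"embedding dimension d={d} must be < n={n}")
    D2 = dist.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:d]
    lam = evals[order]
    V = evecs[:, order]
    warn: list[str] = []
    coords = np.zeros((n, d))
    for a in range(d):
        if lam[a] > 0:
            coords[:, a] = V[:, a] * np.sqrt(lam[a])
        else:
            warn.append(f"axis {a}: non-positive eigenvalue {lam[a]:.3g}, zero-filled")
    if warn:
        warnings.warn("CMDS: " + "; ".join(warn))
    return Lens(kind="extrinsic", algorithm="CMDS", coords=coords,
                params={"d": d}, warnings=warn)


# ---------------------------------------------------------------------------
# Delegation registry for the standard dimensionality reducers.
# Each entry: input form ("distances" | "data"), stochastic flag, and a
# factory(X, d, params, seed) -> coords.  Backends are imported lazily so
# that merely listing the registry stays cheap.
# ---------------------------------------------------------------------------

def _pca(X, d, params, seed):
    from sklearn.decomposition import PCA
    return PCA(n_components=d, svd_solver="full", **params).fit_transform(X)


def _lda(X, d, params, seed):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    p = dict(params)
    labels = p.pop("labels", None)
    if labels is None:
        raise ValueError("LDA requires a 'labels' entry in params")
    return LinearDiscriminantAnalysis(n_components=d, **p).fit_transform(X, labels)


def _factor_analysis(X, d, params, seed):
    from sklearn.decomposition import FactorAnalysis
    return FactorAnalysis(n_components=d, random_state=seed, **params).fit_transform(X)


def _diffusion_maps(X, d, params, seed):
    # Markov-normalized Gaussian kernel on the distance matrix; the map is
    # the top nontrivial right eigenvectors scaled by their eigenvalues.
    p = dict(params)
    eps = p.pop("epsilon", None)
    if eps is None:
        med = np.median(X[X > 0]) if np.any(X > 0) else 1.0
        eps = med ** 2
    K = np.exp(-X ** 2 / eps)
    rowsum = K.sum(axis=1)
    P = K / rowsum[:, None]
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(-evals.real)
    evals, evecs = evals.real[order], evecs.real[:, order]
    return evecs[:, 1:d + 1] * evals[1:d + 1]


def _sammon(X, d, params, seed):
    # Sammon stress minimization by gradient descent with backtracking,
    # initialized from CMDS for determinism.
    D = np.asarray(X, dtype=float)
    n = D.shape[0]
    lens0 = embed_cmds(DistanceMatrix(D, metric_name="precomputed"), d=d)
    Y = lens0.coords.copy()
    eps = 1e-9
    Dm = np.where(D > eps, D, eps)
    np.fill_diagonal(Dm, 1.0)
    scale = D[np.triu_indices(n, 1)].sum() or 1.0
    n_iter = int(params.get("n_iter", 200))

    def stress_grad(Y):
        diff = Y[:, None, :] - Y[None, :, :]
        d_y = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(d_y, 1.0)
        d_y = np.maximum(d_y, eps)
        delta = Dm - d_y
        np.fill_diagonal(delta, 0.0)
        stress = float((delta[np.triu_indices(n, 1)] ** 2 /
                        Dm[np.triu_indices(n, 1)]).sum() / scale)
        g = -2.0 / scale * ((delta / (Dm * d_y))[:, :, None] * diff).sum(axis=1)
        return stress, g

    lr = 0.5
    s, g = stress_grad(Y)
    for _ in range(n_iter):
        Y_new = Y - lr * g
        s_new, g_new = stress_grad(Y_new)
        if s_new < s:
            Y, s, g = Y_new, s_new, g_new
            lr *= 1.1
        else:
            lr *= 0.5
            if lr < 1e-12:
                break
    return Y


def _umap(X, d, params, seed):
    import umap
    p = {"n_neighbors": 15, "min_dist": 0.1, **params}
    return umap.UMAP(n_components=d, random_state=seed, **p).fit_transform(X)


def _isomap(X, d, params, seed):
    from sklearn.manifold import Isomap
    return Isomap(n_components=d, **{"n_neighbors": 10, **params}).fit_transform(X)


def _lle(variant):
    def run(X, d, params, seed):
        from sklearn.manifold import LocallyLinearEmbedding
        p = {"n_neighbors": 10, **params}
        if variant == "hessian":
            # Hessian LLE needs n_neighbors > d * (d + 3) / 2
            p["n_neighbors"] = max(p["n_neighbors"], (d * (d + 3)) // 2 + 1)
        return LocallyLinearEmbedding(
            n_components=d, method=("standard" if variant == "standard" else variant),
            random_state=seed, **p).fit_transform(X)
    return run


def _laplacian(X, d, params, seed):
    from sklearn.manifold import SpectralEmbedding
    return SpectralEmbedding(n_components=d, random_state=seed,
                             **{"n_neighbors": 10, **params}).fit_transform(X)


def _tsne(X, d, params, seed):
    from sklearn.manifold import TSNE
    p = {"perplexity": 20.0, **params}
    return TSNE(n_components=d, metric="precomputed", init="random",
                random_state=seed, **p).fit_transform(X)


#: name -> (input form, stochastic?, backend callable)
EMBEDDING_REGISTRY: dict[str, tuple[str, bool, Callable]] = {
    "CMDS": ("distances", False, None),  # native, special-cased below
    "PCA": ("distances", False, _pca),
    "LDA": ("distances", False, _lda),
    "FactorAnalysis": ("distances", True, _factor_analysis),
    "DiffusionMaps": ("distances", False, _diffusion_maps),
    "Sammon": ("distances", False, _sammon),
    "tSNE": ("distances", True, _tsne),
    "UMAP": ("data", True, _umap),
    "Isomap": ("data", False, _isomap),
    "LLE": ("data", True, _lle("standard")),
    "HessianLLE": ("data", True, _lle("hessian")),
    "Laplacian": ("data", True, _laplacian),
    "LTSA": ("data", True, _lle("ltsa")),
}


def registry_names() -> list[str]:
    return list(EMBEDDING_REGISTRY)


def embed_delegate(data_or_dist: DataMatrix | DistanceMatrix, algorithm: str,
                   d: int = 2, params: dict | None = None,
                   seed: int | None = None) -> Lens:
    """Run a registered dimensionality reducer as the lens.

    The registry declares, per algorithm, whether it consumes the pairwise
    distance matrix or the original data matrix; passing the wrong form is
    an error.  Stochastic algorithms require ``seed``; a fixed seed and
    fixed input give byte-identical coordinates.
    """
    params = dict(params or {})
    if algorithm not in EMBEDDING_REGISTRY:
        raise ValueError(
            f"unknown embedding {algorithm!r}; registered: {registry_names()}")
    input_form, stochastic, backend = EMBEDDING_REGISTRY[algorithm]
    if input_form == "distances":
        if not isinstance(data_or_dist, DistanceMatrix):
            raise ValueError(f"{algorithm} is applied on pairwise distances; "
                             "pass a DistanceMatrix")
        X = data_or_dist.values
    else:
        if not isinstance(data_or_dist, DataMatrix):
            raise ValueError(f"{algorithm} is applied on the original data; "
                             "pass a DataMatrix")
        X = data_or_dist.values
    if stochastic and seed is None:
        raise ValueError(f"{algorithm} is stochastic; a seed is required")
    if algorithm == "CMDS":
        lens = embed_cmds(data_or_dist, d=d)
        lens.params.update(params)
        return lens
    coords = np.asarray(backend(X, d, params, seed), dtype=float)
    return Lens(kind="extrinsic", algorithm=algorithm, coords=coords,
                params={"d": d, "seed": seed, **params})


def intrinsic_lens(graph: NeighborGraph, mode: str = "weighted") -> Lens:
    """Lens that is the k-NN graph itself plus its geodesic distances."""
    geo = geodesic_distances(graph, mode=mode)
    return Lens(kind="intrinsic", algorithm="knn-graph", graph=graph, geo=geo,
                params={"mode": mode})
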