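"""Per-view clustering ensembles from noise-perturbed data.

Within each view the clustering algorithm is run once on the original data
(the *reference partition*) and m more times on copies perturbed with
isotropic Gaussian noise, N(0, sigma^2 I) added independently to every
point.  The noise variance is tied to the data scale: by default 10% of
the average within-cluster variance of the reference clustering, so the
perturbation probes genuine assignment uncertainty rather than an
arbitrary noise floor.  Views flagged as unperturbed (e.g. a dominant
modality whose clustering should be taken at face value) get m re-runs of
the clusterer on the original data under distinct seeds instead.

Any clustering algorithm can be plugged in through the ``(X, seed) ->
labels`` callable contract; k-means, Gaussian-mixture, and Leiden on a
kNN graph are built in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .partitions import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "ViewData",
    "ClustererSpec",
    "make_clusterer",
    "avg_within_cluster_variance",
    "perturb",
    "build_ensemble",
]


@dataclass
class ViewData:
    """One view's numeric feature matrix (items x features)."""

    X: np.ndarray
    name: str = "view"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"view {self.name}: expected a 2-D matrix, got ndim={X.ndim}")
        if not np.all(np.isfinite(X)):
            raise ValueError(f"view {self.name}: non-finite entries")
        self.X = X

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ClustererSpec:
    """A deterministic-given-seed clustering algorithm: (X, seed) -> labels."""

    fn: Callable[[np.ndarray, int], np.ndarray]
    name: str = "clusterer"

    def __call__(self, X: np.ndarray, seed: int) -> Partition:
        labels = np.asarray(self.fn(X, seed))
        if labels.shape != (X.shape[0],):
            raise ValueError(
                f"clusterer {self.name} returned labels of shape {labels.shape}, expected ({X.shape[0]},)")
        return Partition(labels)


def _kmeans(n_clusters: int, **kw) -> Callable:
    from sklearn.cluster import KMeans

    def fn(X, seed):
        return KMeans(n_clusters=n_clusters, random_state=seed, n_init=10, **kw).fit_predict(X) + 1

    return fn


def _gmm(n_components: int, **kw) -> Callable:
    from sklearn.mixture import GaussianMixture

    def fn(X, seed):
        return GaussianMixture(n_components=n_components, random_state=seed, **kw).fit_predict(X) + 1

    return fn


def _leiden_knn(n_neighbors: int = 15, resolution: float = 1.0, **kw) -> Callable:
    """Graph clustering on a kNN graph, the Seurat-style default."""

    def fn(X, seed):
        import igraph
        import leidenalg
        from sklearn.neighbors import kneighbors_graph

        adj = kneighbors_graph(X, n_neighbors=min(n_neighbors, X.shape[0] - 1), mode="connectivity")
        adj = adj.maximum(adj.T).tocoo()
        edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
        g = igraph.Graph(n=X.shape[0], edges=edges)
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=int(seed), **kw)
        return np.asarray(part.membership) + 1

    return fn


_CLUSTERERS = {"kmeans": _kmeans, "gmm": _gmm, "leiden": _leiden_knn}


def make_clusterer(name: str, **params) -> ClustererSpec:
    """Built-in clusterer by name: ``kmeans``, ``gmm``, or ``leiden``."""
    if name not in _CLUSTERERS:
        raise ValueError(f"unknown clusterer {name!r}; choose from {sorted(_CLUSTERERS)}")
    return ClustererSpec(fn=_CLUSTERERS[name](**params), name=name)


def avg_within_cluster_variance(view: ViewData, partition: Partition) -> float:
    """Average within-cluster variance of a clustered view.

    Defined as the unweighted mean over clusters of the mean across
    coordinates of the per-coordinate sample variance (denominator
    ``n_k - 1``); singleton clusters contribute 0.  Scale-free across K and
    d: scaling X by c scales the result by c^2.
    """
    if partition.n != view.n:
        raise ValueError("partition does not match the view's rows")
    per_cluster = []
    for k in range(1, partition.K + 1):
        rows = view.X[partition.members(k)]
        if rows.shape[0] < 2:
            per_cluster.append(0.0)
            continue
        per_cluster.append(float(np.mean(np.var(rows, axis=0, ddof=1))))
    if all(v == 0.0 for v in per_cluster):
        logger.warning("avg_within_cluster_variance: all clusters degenerate; returning 0")
    return float(np.mean(per_cluster))


def perturb(view: ViewData, variance: float, seed: int) -> ViewData:
    """Add isotropic Gaussian noise N(0, variance * I) to every point."""
    if variance < 0:
        raise ValueError(f"variance must be >= 0, got {variance}")
    if variance == 0:
        return ViewData(view.X.copy(), view.name)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(variance), size=view.X.shape)
    return ViewData(view.X + noise, view.name)


def build_ensemble(view: ViewData, clusterer: ClustererSpec, m: int,
                   noise_fraction: float = 0.1, seed: int = 0,
                   perturb_this_view: bool = True) -> tuple[Partition, list[Partition]]:
    """Reference partition plus m raw partitions of noise-perturbed copies.

    The noise variance is ``noise_fraction`` times the average within-cluster
    variance of the reference clustering.  Per-partition seeds are
    ``seed + p`` (p = 1..m), so a master seed fixes the whole ensemble.
    With ``perturb_this_view=False`` the m partitions are clusterer re-runs
    on the unperturbed data under those distinct seeds.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    try:
        reference = clusterer(view.X, seed)
    except Exception as exc:
        raise RuntimeError(f"reference clustering failed for view {view.name}: {exc}") from exc
    variance = noise_fraction * avg_within_cluster_variance(view, reference) if perturb_this_view else 0.0
    raw: list[Partition] = []
    for p in range(1, m + 1):
        Xp = perturb(view, variance, seed + p) if perturb_this_view else view
        try:
            raw.append(clusterer(Xp.X, seed + p))
        except Exception as exc:
            raise RuntimeError(f"clustering failed for view {view.name}, perturbation {p}: {exc}") from exc
    return reference, raw
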