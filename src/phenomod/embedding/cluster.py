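"""K-means and hierarchical clustering of observation matrices.

K-means is Lloyd's algorithm with k-means++ initialization, 10 seeded
restarts keeping the lowest within-cluster sum of squares, and an
exposed per-iteration WSS trace (non-increasing by construction).
Hierarchical clustering wraps scipy's linkage; the merge tree and leaf
order are returned so a heatmap layer can reorder the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import kmeans_plusplus

from ..exceptions import ValidationError
from .embed import DataMatrix

__all__ = ["ClusteringResult", "kmeans_cluster", "hclust_cluster", "cluster_features"]


@dataclass
class ClusteringResult:
    method: str
    labels: np.ndarray          # cluster ids, 1-based for kmeans
    extras: dict = field(default_factory=dict)


def _lloyd(X, centers, max_iter=300, tol=1e-10):
    trace = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(1)
        wss = float(d2[np.arange(X.shape[0]), labels].sum())
        trace.append(wss)
        new = centers.copy()
        for j in range(centers.shape[0]):
            members = X[labels == j]
            if members.size:
                new[j] = members.mean(0)
        if np.allclose(new, centers, atol=tol, rtol=0):
            centers = new
            break
        centers = new
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    labels = d2.argmin(1)
    wss = float(d2[np.arange(X.shape[0]), labels].sum())
    trace.append(wss)
    return labels, centers, wss, trace


def kmeans_cluster(matrix: DataMatrix, k: int, seed: int = 0,
                   n_starts: int = 10) -> ClusteringResult:
    """Seeded multi-start k-means; the best (lowest-WSS) run is kept."""
    X = matrix.values
    if not (1 <= k <= matrix.n):
        raise ValidationError(f"k must be in [1, {matrix.n}]")
    rng = np.random.default_rng(int(seed) % (2**31))
    best = None
    for start in range(n_starts):
        centers, _ = kmeans_plusplus(
            X, n_clusters=k, random_state=int(rng.integers(2**31)))
        labels, centers, wss, trace = _lloyd(X, centers.astype(float))
        if best is None or wss < best[2] - 1e-12:
            best = (labels, centers, wss, trace)
    labels, centers, wss, trace = best
    # relabel clusters 1..k in order of first appearance (non-empty kept)
    remap, next_id = {}, 1
    out = np.empty(labels.shape, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = next_id
            next_id += 1
        out[i] = remap[lab]
    order = sorted(remap, key=remap.get)
    return ClusteringResult(
        "kmeans", out,
        extras={"centers": centers[order], "wss": wss, "wss_trace": trace,
                "k": k, "seed": seed},
    )


def hclust_cluster(matrix: DataMatrix, linkage: str = "average",
                   distance: str = "euclidean", k: int | None = None) -> ClusteringResult:
    """Agglomerative clustering; returns merge tree, leaf order, labels."""
    if linkage not in ("complete", "average", "ward"):
        raise ValidationError("linkage must be complete|average|ward")
    X = matrix.values
    if distance == "correlation":
        d = pdist(X, metric="correlation")
    elif distance == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite distances")
    Z = hierarchy.linkage(d, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    labels = (hierarchy.fcluster(Z, t=k, criterion="maxclust")
              if k is not None else np.ones(matrix.n, dtype=int))
    return ClusteringResult(
        "hclust", labels,
        extras={"merge_tree": Z, "leaf_order": leaves,
                "leaf_ids": [matrix.row_ids[i] for i in leaves],
                "linkage": linkage, "distance": distance},
    )


def cluster_features(matrix: DataMatrix, method: str, *, k: int | None = None,
                     linkage: str = "average", distance: str = "euclidean",
                     seed: int = 0) -> ClusteringResult:
    """Dispatch to k-means or hierarchical clustering."""
    if method == "kmeans":
        if k is None:
            raise ValidationError("kmeans requires k")
        return kmeans_cluster(matrix, k, seed)
    if method == "hclust":
        return hclust_cluster(matrix, linkage, distance, k)
    raise ValidationError(f"unknown clustering method {method!r}")
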