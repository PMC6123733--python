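"""Low-dimensional embeddings of observation × feature matrices.

PCA is computed by SVD of the column-centered (optionally unit-scaled)
matrix; biplot loadings are reported as the Pearson correlations between
each original column and each component score, alongside the raw
eigenvectors.  t-SNE is delegated to scikit-learn behind a deterministic
seeded contract.  MDS is classical (Torgerson) scaling of a euclidean or
correlation distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ..exceptions import ValidationError

__all__ = ["DataMatrix", "EmbeddingResult", "pca_embed", "tsne_embed", "mds_embed"]


@dataclass
class DataMatrix:
    """Numeric matrix of n observations × p features with identifiers."""

    row_ids: list
    column_ids: list
    values: np.ndarray
    row_annotations: dict = field(default_factory=dict)
    column_annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = X.shape
        if n < 2 or p < 2:
            raise ValidationError(f"need n >= 2 and p >= 2, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("matrix contains non-finite values")
        if len(self.row_ids) != n or len(self.column_ids) != p:
            raise ValidationError("id vectors inconsistent with matrix shape")
        self.values = X

    @property
    def n(self):
        return self.values.shape[0]

    @property
    def p(self):
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df, annotations=None):
        feats = df.select_dtypes(include=[np.number])
        return cls([str(r) for r in df.index], list(feats.columns),
                   feats.to_numpy(dtype=float),
                   row_annotations=annotations or {})


@dataclass
class EmbeddingResult:
    """Coordinates plus method-specific extras (loadings, codebook, ...)."""

    method: str
    coordinates: np.ndarray     # n × d
    row_ids: list
    extras: dict = field(default_factory=dict)

    @property
    def n_dims(self):
        return self.coordinates.shape[1]


def pca_embed(matrix: DataMatrix, n_components: int, scale: bool = False) -> EmbeddingResult:
    """Principal component scores, correlation loadings and variance shares.

    ``variance_explained`` holds the ratio for the returned components;
    the full spectrum over all min(n-1, p) components (which sums to 1)
    is in ``extras["variance_explained_full"]``.
    """
    X = matrix.values
    max_comp = min(matrix.n - 1, matrix.p)
    if not (1 <= n_components <= max_comp):
        raise ValidationError(f"n_components must be in [1, {max_comp}]")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if zero.size:
            raise ValidationError(
                f"zero-variance column(s) with scale=True: "
                f"{[matrix.column_ids[j] for j in zero[:5]]}"
            )
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|entry| eigenvector coordinate positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S**2
    ratio_full = var[:max_comp] / var[:max_comp].sum()
    scores = U[:, :n_components] * S[:n_components]
    eigvec = Vt[:n_components].T                      # p × d
    # biplot loadings: correlation of each original column with each score
    loadings = np.zeros((matrix.p, n_components))
    score_sd = scores.std(axis=0, ddof=1)
    col_sd = Xc.std(axis=0, ddof=1)
    for d in range(n_components):
        if score_sd[d] == 0:
            continue
        cov = (Xc * (scores[:, d] - scores[:, d].mean())[:, None]).sum(0) / (matrix.n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings[:, d] = np.where(col_sd > 0, cov / (col_sd * score_sd[d]), 0.0)
    return EmbeddingResult(
        "pca", scores, list(matrix.row_ids),
        extras={
            "loadings": loadings,
            "eigenvectors": eigvec,
            "variance_explained": ratio_full[:n_components],
            "variance_explained_full": ratio_full,
            "column_ids": list(matrix.column_ids),
            "mean": X.mean(axis=0),
            "scale": scale,
        },
    )


def tsne_embed(matrix: DataMatrix, dims: int = 2, perplexity: float = 30.0,
               seed: int = 0) -> EmbeddingResult:
    """t-SNE projection to 2 or 3 dimensions, deterministic given the seed."""
    if dims not in (2, 3):
        raise ValidationError("dims must be 2 or 3")
    limit = (matrix.n - 1) / 3.0
    if not (0 < perplexity < limit):
        raise ValidationError(
            f"perplexity must lie in (0, {limit:.3g}) for n={matrix.n}"
        )
    from sklearn.manifold import TSNE

    coords = TSNE(
        n_components=dims, perplexity=perplexity, random_state=int(seed) % (2**31),
        init="pca", method="exact" if matrix.n < 100 else "barnes_hut",
    ).fit_transform(matrix.values)
    return EmbeddingResult("tsne", np.asarray(coords, dtype=float),
                           list(matrix.row_ids),
                           extras={"perplexity": perplexity, "seed": seed})


def _distance_matrix(X, distance):
    if distance == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif distance == "correlation":
        sd = X.std(axis=1)
        if np.any(sd == 0):
            raise ValidationError("correlation distance undefined for constant rows")
        D = squareform(pdist(X, metric="correlation"))
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    if not np.all(np.isfinite(D)):
        raise ValidationError("non-finite distances")
    return D


def mds_embed(matrix: DataMatrix, dims: int = 2,
              distance: str = "euclidean") -> EmbeddingResult:
    """Classical (Torgerson) multidimensional scaling.

    For euclidean distances of data of true dimension <= dims the
    embedded pairwise distances reproduce the input exactly (up to
    rotation/reflection).
    """
    if not (1 <= dims <= matrix.n - 1):
        raise ValidationError(f"dims must be in [1, {matrix.n - 1}]")
    D = _distance_matrix(matrix.values, distance)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = np.clip(eigval[:dims], 0.0, None)
    coords = eigvec[:, :dims] * np.sqrt(lam)
    for j in range(dims):  # deterministic sign convention
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1.0
    return EmbeddingResult("mds", coords, list(matrix.row_ids),
                           extras={"distance": distance, "eigenvalues": eigval})
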