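"""Self-organizing map on a rectangular grid.

A small batch SOM: the codebook starts on the plane spanned by the first
two principal components (plus a seeded jitter to break degeneracies)
and is refined by batch updates with a Gaussian neighborhood whose
radius shrinks over epochs.  Training is a pure function of
(input, grid shape, seed), so results are reproducible bit for bit.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ValidationError
from .embed import DataMatrix, EmbeddingResult

__all__ = ["som_fit", "pca_som"]


def _init_codebook(X, rows, cols, rng):
    Xc = X - X.mean(axis=0)
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    g = np.stack(np.meshgrid(np.linspace(-1, 1, rows), np.linspace(-1, 1, cols),
                             indexing="ij"), axis=-1).reshape(-1, 2)
    if Vt.shape[0] >= 2:
        span = g[:, :1] * (S[0] / 2) * Vt[0] + g[:, 1:2] * (S[1] / 2) * Vt[1]
    else:
        span = g[:, :1] * (S[0] / 2) * Vt[0]
    code = X.mean(axis=0) + span / np.sqrt(max(X.shape[0] - 1, 1))
    code = code + rng.normal(0.0, 1e-6 * (X.std() + 1e-12), code.shape)
    return code


def _bmu(X, code):
    d2 = ((X[:, None, :] - code[None, :, :]) ** 2).sum(-1)
    return np.argmin(d2, axis=1)


def som_fit(matrix: DataMatrix, grid_rows: int, grid_cols: int,
            seed: int = 0, n_epochs: int = 30) -> EmbeddingResult:
    """Train a (grid_rows × grid_cols) SOM and assign best-matching units.

    Coordinates returned per observation are the (row, col) grid position
    of its best-matching unit; the codebook and node assignment are in
    ``extras``.
    """
    X = matrix.values
    n_nodes = grid_rows * grid_cols
    if grid_rows < 1 or grid_cols < 1:
        raise ValidationError("grid dimensions must be positive")
    if n_nodes > matrix.n:
        raise ValidationError(
            f"grid has {n_nodes} nodes but only {matrix.n} observations"
        )
    rng = np.random.default_rng(int(seed) % (2**31))
    code = _init_codebook(X, grid_rows, grid_cols, rng)
    grid = np.stack(np.meshgrid(np.arange(grid_rows), np.arange(grid_cols),
                                indexing="ij"), axis=-1).reshape(-1, 2).astype(float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
    sigma0 = max(grid_rows, grid_cols) / 2.0
    for epoch in range(n_epochs):
        sigma = max(sigma0 * (1.0 - epoch / n_epochs), 0.4)
        bmu = _bmu(X, code)
        h = np.exp(-grid_d2[:, bmu] / (2.0 * sigma**2))     # nodes × samples
        weights = h.sum(axis=1, keepdims=True)
        nonzero = weights[:, 0] > 1e-12
        code[nonzero] = (h @ X)[nonzero] / weights[nonzero]
    assignment = _bmu(X, code)
    coords = grid[assignment]
    return EmbeddingResult(
        "som", coords, list(matrix.row_ids),
        extras={"codebook": code, "assignment": assignment,
                "grid": (grid_rows, grid_cols), "seed": seed},
    )


def pca_som(matrix: DataMatrix, n_components: int, grid_rows: int,
            grid_cols: int, seed: int = 0) -> EmbeddingResult:
    """SOM trained on PCA scores (dimensionality reduction first)."""
    from .embed import pca_embed

    scores = pca_embed(matrix, n_components)
    reduced = DataMatrix(list(matrix.row_ids),
                         [f"PC{i+1}" for i in range(n_components)],
                         scores.coordinates)
    res = som_fit(reduced, grid_rows, grid_cols, seed)
    res.method = "pca_som"
    res.extras["n_components"] = n_components
    return res
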