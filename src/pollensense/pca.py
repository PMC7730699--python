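"""Principal component analysis via singular value decomposition."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PCAResults:
    """Scores, loadings and explained variance of a fitted PCA.

    ``loadings`` columns are orthonormal directions of successively maximal
    variance; ``scores = (X − mean) @ loadings``; ``explained_variance_pct``
    is non-increasing and sums to at most 100.
    """

    mean: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_pct: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings.T + self.mean


def fit_pca(X: np.ndarray, n_components: int | None = None) -> PCAResults:
    """Fit a PCA on the rows of ``X`` (centering is done internally).

    Requests beyond the matrix rank are truncated with a warning.  The sign
    of each loading vector is fixed so that its largest-magnitude element is
    positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_rank = min(n - 1, p)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components but the data support at most "
            f"{max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    if n_components < 1:
        raise ValueError("need at least one component and two observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # effective rank truncation: components with ~zero singular value carry
    # no variance and have arbitrary direction
    tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if n_components > rank:
        warnings.warn(
            f"rank-deficient data (rank {rank}); truncating from "
            f"{n_components} components",
            stacklevel=2,
        )
        n_components = max(rank, 1)
    s = s[:n_components]
    V = Vt[:n_components].T
    # deterministic sign
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = Xc @ V
    var = s**2 / (n - 1)
    total_var = Xc.var(axis=0, ddof=1).sum()
    pct = 100.0 * var / total_var if total_var > 0 else np.zeros_like(var)
    return PCAResults(mean, scores, V, var, pct)
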