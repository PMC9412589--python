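"""Unsupervised sample-structure screen: Spearman dissimilarity, classical
(Torgerson) multidimensional scaling, k-means clustering and outlier flagging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from csfpanel.errors import AnalysisError
from csfpanel.ingest import IntensityMatrix


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame          # samples x k
    eigenvalues: np.ndarray            # all eigenvalues, non-increasing
    cluster_labels: pd.Series | None = None
    outlier_flags: pd.Series | None = None


def spearman_correlation(matrix: IntensityMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation between samples."""
    corr = matrix.values.corr(method="spearman", min_periods=min_shared)
    bad = corr.isna().to_numpy()
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AnalysisError(
            f"samples '{corr.index[i]}' and '{corr.columns[j]}' share fewer than {min_shared} detected proteins"
        )
    return corr


def spearman_dissimilarity(matrix: IntensityMatrix, min_shared: int = 3) -> pd.DataFrame:
    """d = 1 - rho on pairwise-complete detected values; symmetric, zero diagonal."""
    corr = spearman_correlation(matrix, min_shared=min_shared)
    d = 1.0 - corr
    arr = d.to_numpy()
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    return pd.DataFrame(arr, index=d.index, columns=d.columns)


def classical_mds(dissimilarities: pd.DataFrame, k: int = 2) -> EmbeddingResult:
    """Torgerson classical MDS: double-centered Gram eigendecomposition.

    Coordinates use the top-k positive-eigenvalue axes; each axis is oriented
    so that its largest-magnitude coordinate is positive.
    """
    D = np.asarray(dissimilarities, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise AnalysisError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise AnalysisError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    if eigvals[0] <= tol:
        raise AnalysisError("degenerate geometry: no positive eigenvalue in the Gram matrix")
    n_pos = int(np.sum(eigvals > tol))
    k_eff = min(k, n_pos)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    if k_eff < k:
        coords = np.hstack([coords, np.zeros((n, k - k_eff))])
    for a in range(coords.shape[1]):
        col = coords[:, a]
        if np.any(col != 0) and col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    frame = pd.DataFrame(coords, index=dissimilarities.index, columns=[f"MDS{a + 1}" for a in range(k)])
    return EmbeddingResult(coordinates=frame, eigenvalues=eigvals)


def kmeans_clusters(
    coordinates: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 50
) -> pd.Series:
    """k-means++ labels (best inertia over restarts), deterministic under seed."""
    if k < 1:
        raise AnalysisError("k must be >= 1")
    if k > len(coordinates):
        raise AnalysisError(f"k={k} exceeds sample count {len(coordinates)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(np.asarray(coordinates, dtype=float))
    return pd.Series(labels, index=coordinates.index, name="cluster")


def flag_outliers(matrix: IntensityMatrix, n_mads: float = 3.0, min_shared: int = 3) -> pd.Series:
    """Flag samples whose median Spearman correlation to all other samples
    falls more than ``n_mads`` (consistency-scaled) MADs below the cohort
    median of that statistic."""
    corr = spearman_correlation(matrix, min_shared=min_shared).to_numpy()
    np.fill_diagonal(corr, np.nan)
    med_per_sample = np.nanmedian(corr, axis=1)
    center = np.median(med_per_sample)
    mad = 1.4826 * np.median(np.abs(med_per_sample - center))
    flags = med_per_sample < center - n_mads * mad
    return pd.Series(flags, index=matrix.sample_ids, name="outlier")


def embed_samples(
    matrix: IntensityMatrix, k_clusters: int = 8, k_dims: int = 2, seed: int = 0, n_restarts: int = 50
) -> EmbeddingResult:
    """Full screen: Spearman dissimilarity -> classical MDS -> k-means + outlier flags."""
    d = spearman_dissimilarity(matrix)
    result = classical_mds(d, k=k_dims)
    result.cluster_labels = kmeans_clusters(result.coordinates, k_clusters, seed=seed, n_restarts=n_restarts)
    result.outlier_flags = flag_outliers(matrix)
    return result
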