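"""Normalized spectral clustering of the standardized feature matrix.

The database is partitioned once at build time: a Gaussian similarity graph
W_ij = exp(-||x_i - x_j||^2 / (2 delta^2)) is formed over the training
vectors, the symmetric normalized Laplacian L = D^{-1/2} (D - W) D^{-1/2}
is eigendecomposed, and seeded k-means on the row-normalized embedding of
the k bottom eigenvectors (the Ng-Jordan-Weiss variant) yields the
partition.  Cluster centers are recomputed as means in the *original*
standardized feature space, because queries are pruned by their feature-
space distance to the centers, never embedded.

Dense eigendecomposition is used throughout: databases here are at most a
few thousand images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class ClusterModel:
    """A k-way partition of the training set with feature-space centers."""

    centers: np.ndarray  # (k, d) means in standardized feature space
    assignments: np.ndarray  # (n,) cluster index in {0..k-1}
    delta: float  # similarity bandwidth used to build W
    k: int

    def __post_init__(self) -> None:
        if self.centers.shape[0] != self.k:
            raise ValueError("centers must have k rows")
        counts = np.bincount(self.assignments, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be nonempty")


def similarity_matrix(X: np.ndarray, delta: float) -> np.ndarray:
    """Gaussian affinity W_ij = exp(-||x_i-x_j||^2 / (2 delta^2)); diagonal 1."""
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1)
    W = np.exp(-sq / (2.0 * delta**2))
    return (W + W.T) / 2.0  # enforce exact symmetry against rounding


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian L = D^{-1/2} (D - W) D^{-1/2}.

    D is diagonal with the row sums of W.  L is symmetric positive
    semidefinite with D^{1/2} 1 in its null space.
    """
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    if (d <= 0).any():
        raise ValueError("every row of W must have a positive sum")
    inv_sqrt = 1.0 / np.sqrt(d)
    L = -W * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(L, np.diag(L) + 1.0)  # D^{-1/2} D D^{-1/2} = I
    return (L + L.T) / 2.0


def median_pairwise_distance(X: np.ndarray, seed: int = 0, subsample: int = 200) -> float:
    """Median Euclidean pairwise distance over a seeded subsample.

    The default similarity bandwidth delta: scale-free and robust to the
    feature mix.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if X.shape[0] > subsample:
        idx = rng.choice(X.shape[0], subsample, replace=False)
        X = X[idx]
    from scipy.spatial.distance import pdist

    d = pdist(X)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def spectral_cluster(
    X: np.ndarray,
    k: int,
    delta: float | None = None,
    seed: int = 0,
) -> ClusterModel:
    """Partition rows of X into k clusters by normalized spectral clustering.

    The n x k embedding of the k smallest-eigenvalue eigenvectors of L is
    row-normalized and clustered by seeded k-means (10 restarts); centers are
    then recomputed as per-cluster means of the original rows.  If k-means
    leaves a cluster empty it is re-seeded, up to 5 attempts.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, n={n}]")
    if k == 1:
        return ClusterModel(
            centers=X.mean(axis=0, keepdims=True),
            assignments=np.zeros(n, dtype=int),
            delta=float(delta or 1.0),
            k=1,
        )
    if delta is None:
        delta = median_pairwise_distance(X, seed=seed)
    W = similarity_matrix(X, delta)
    L = normalized_laplacian(W)
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = vecs / norms

    labels = None
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        cand = km.fit_predict(emb)
        if len(np.unique(cand)) == k:
            labels = cand
            break
    if labels is None:
        raise RuntimeError("k-means produced an empty cluster in 5 seeded attempts")

    centers = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterModel(centers=centers, assignments=labels, delta=float(delta), k=k)
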