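"""Low-dimensional embedding and clustering of learned similarities.

The learned similarity matrix S is embedded with t-SNE, feeding the
symmetrized and globally normalized S directly in as the joint-probability
affinity matrix rather than recomputing affinities from distances.  The
gradient descent is the standard Kullback-Leibler minimization with a
Student-t low-dimensional kernel, early exaggeration and momentum.  Subjects
are clustered by k-means on the spectral latent matrix; Ward's hierarchical
clustering provides the classical agglomerative baseline.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering, KMeans

_MACHINE_EPS = 1e-12


def affinity_from_similarity(S: np.ndarray) -> np.ndarray:
    """Symmetrize S and normalize it to a joint probability matrix."""
    S = np.asarray(S, dtype=float)
    P = (S + S.T) / 2.0
    np.fill_diagonal(P, 0.0)
    total = P.sum()
    if total <= 0:
        raise ValueError("similarity matrix has zero total mass")
    P = P / total
    return np.maximum(P, _MACHINE_EPS)


def embed(S: np.ndarray, dims: int = 2, seed: int = 0, n_iter: int = 500,
          learning_rate: float = 200.0, early_exaggeration: float = 12.0) -> np.ndarray:
    """t-SNE embedding of a similarity matrix used as precomputed affinities.

    Deterministic given ``seed``; returns an n x dims array.
    """
    P = affinity_from_similarity(S)
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    Y = 1e-4 * rng.standard_normal((n, dims))
    update = np.zeros_like(Y)
    exaggeration_until = min(250, n_iter // 2)
    for it in range(n_iter):
        Pit = P * early_exaggeration if it < exaggeration_until else P
        D2 = squareform(pdist(Y)) ** 2
        W = 1.0 / (1.0 + D2)
        np.fill_diagonal(W, 0.0)
        Q = np.maximum(W / W.sum(), _MACHINE_EPS)
        # dC/dy_i = 4 sum_j (p_ij - q_ij) w_ij (y_i - y_j)
        M = (Pit - Q) * W
        grad = 4.0 * ((np.diag(M.sum(axis=1)) - M) @ Y)
        momentum = 0.5 if it < exaggeration_until else 0.8
        update = momentum * update - learning_rate * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
    return Y


def cluster_latent(L: np.ndarray, c: int, seed: int = 0, restarts: int = 50) -> np.ndarray:
    """K-means on the rows of the latent matrix; labels in [0, c)."""
    L = np.asarray(L, dtype=float)
    if c > L.shape[0]:
        raise ValueError(f"c={c} exceeds the number of subjects {L.shape[0]}")
    km = KMeans(n_clusters=c, n_init=restarts, random_state=seed)
    return km.fit_predict(L)


def ward_cluster(features: np.ndarray, c: int) -> np.ndarray:
    """Agglomerative clustering with Ward's criterion, cut at c clusters."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < c:
        raise ValueError("fewer subjects than requested clusters")
    model = AgglomerativeClustering(n_clusters=c, linkage="ward")
    return model.fit_predict(features)
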