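"""Adaptive-bandwidth Gaussian subject-similarity kernels.

Each kernel compares two subjects' connectional feature vectors with a
Gaussian whose bandwidth adapts to local sampling density:

    K(h_i, h_j) = 1 / (eps_ij sqrt(2 pi)) * exp(-||h_i - h_j||^2 / (2 eps_ij^2))

with ``eps_ij = sigma (mu_i + mu_j) / 2`` where ``mu_i`` is the mean
Euclidean distance from subject *i* to its ``k`` nearest neighbors (self
excluded) and ``sigma`` a global tuning parameter.  A bank enumerates a grid
of (sigma, k) settings; the default grid sigma in {1.0, 1.25, ..., 2.5} by
k in {10, 12, 14} yields m = 21 kernels.

Raw kernels carry the 1/(eps sqrt(2 pi)) density prefactor and are therefore
not scale-commensurable across bandwidths; `normalize_kernel` rescales each
to a symmetrized degree-normalized form before any weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

DEFAULT_SIGMA_GRID = (1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5)
DEFAULT_K_GRID = (10, 12, 14)

_EPS_FLOOR_FACTOR = 1e-12


@dataclass(frozen=True)
class KernelParams:
    sigma: float
    k_neighbors: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class KernelBank:
    """m symmetric nonnegative n x n kernels with their grid parameters."""

    kernels: np.ndarray  # m x n x n
    params: list[KernelParams]

    @property
    def m(self) -> int:
        return self.kernels.shape[0]

    @property
    def n(self) -> int:
        return self.kernels.shape[1]


def pairwise_distances(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be an n x d matrix")
    return squareform(pdist(features)) if features.shape[0] > 1 else np.zeros((1, 1))


def neighbor_scale(features: np.ndarray, k_neighbors: int, D: np.ndarray | None = None) -> np.ndarray:
    """mu_i = mean Euclidean distance from subject i to its k nearest neighbors."""
    if D is None:
        D = pairwise_distances(features)
    n = D.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n={n}")
    # sort each row; column 0 is the zero self-distance
    Ds = np.sort(D, axis=1)
    return Ds[:, 1 : k_neighbors + 1].mean(axis=1)


def gaussian_kernel(
    features: np.ndarray, params: KernelParams, D: np.ndarray | None = None
) -> np.ndarray:
    """Adaptive-bandwidth Gaussian kernel for one (sigma, k) setting.

    Degenerate local scales (duplicate subjects give mu_i = 0) are handled by
    flooring eps_ij at ``1e-12 x mean pairwise distance`` (or 1e-12 if every
    distance is 0) so duplicates do not produce infinite density.
    """
    if D is None:
        D = pairwise_distances(features)
    mu = neighbor_scale(features, params.k_neighbors, D=D)
    eps = params.sigma * (mu[:, None] + mu[None, :]) / 2.0
    mean_dist = D[np.triu_indices_from(D, k=1)].mean() if D.shape[0] > 1 else 0.0
    floor = _EPS_FLOOR_FACTOR * (mean_dist if mean_dist > 0 else 1.0)
    eps = np.maximum(eps, floor)
    if np.any(eps == 0):
        raise ValueError("zero kernel bandwidth after flooring")
    K = np.exp(-(D**2) / (2.0 * eps**2)) / (eps * np.sqrt(2.0 * np.pi))
    return (K + K.T) / 2.0


def build_kernel_bank(
    features: np.ndarray,
    sigma_grid=DEFAULT_SIGMA_GRID,
    k_grid=DEFAULT_K_GRID,
    normalize: bool = True,
) -> KernelBank:
    """One kernel per (sigma, k) grid point, ordered sigma-major."""
    sigma_grid = list(sigma_grid)
    k_grid = list(k_grid)
    if not sigma_grid or not k_grid:
        raise ValueError("sigma_grid and k_grid must be non-empty")
    D = pairwise_distances(np.asarray(features, dtype=float))
    params = [KernelParams(s, k) for s in sigma_grid for k in k_grid]
    kernels = []
    for p in params:
        K = gaussian_kernel(features, p, D=D)
        kernels.append(normalize_kernel(K) if normalize else K)
    return KernelBank(kernels=np.stack(kernels), params=params)


def normalize_kernel(K: np.ndarray) -> np.ndarray:
    """Symmetrized degree normalization D^{-1/2} K D^{-1/2}."""
    K = np.asarray(K, dtype=float)
    d = K.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("kernel has a non-positive row sum")
    inv_sqrt = 1.0 / np.sqrt(d)
    M = K * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (M + M.T) / 2.0
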