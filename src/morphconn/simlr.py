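"""Multi-kernel similarity learning by alternating convex optimization.

Given a bank of m normalized subject-similarity kernels K_l, learn a
row-stochastic similarity matrix S, an orthonormal spectral latent matrix L
(n x c) and kernel weights w on the simplex by minimizing

    F(S, L, w) = - sum_l w_l <K_l, S>  +  beta ||S||_F^2
                 + gamma tr(L' (I_n - S) L)  +  rho sum_l w_l log w_l

subject to  sum_j S_ij = 1, S_ij >= 0,  sum_l w_l = 1, w_l >= 0,  L'L = I_c.

Each block has an exact coordinate update:

* L — the c bottom eigenvectors of the Laplacian I_n - (S + S') / 2;
* w — an entropic softmax, w_l proportional to exp(<K_l, S> / rho);
* S — row-wise Euclidean projection of a_i / (2 beta) onto the probability
  simplex, where a_ij = sum_l w_l K_l(i, j) + gamma (L L')_ij.

Because every update is an exact minimizer of its block, the objective trace
is monotone non-increasing over full cycles when graph diffusion is off.
Optional KNN-truncated graph diffusion between cycles strengthens weak
within-cluster similarities (at the cost of the monotonicity guarantee).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .kernels import DEFAULT_K_GRID, DEFAULT_SIGMA_GRID, KernelBank, build_kernel_bank


@dataclass
class SimlrConfig:
    """Hyperparameters of the alternating optimization."""

    c: int = 4
    beta: float = 0.8
    gamma: float = 1.0
    rho: float = 1.0
    max_iter: int = 30
    tol: float = 1e-6
    diffusion_knn: int = 12
    diffusion_steps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least c = 2 clusters")
        for name in ("beta", "gamma", "rho", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.diffusion_steps < 0:
            raise ValueError("diffusion_steps must be >= 0")


@dataclass
class SimlrState:
    S: np.ndarray
    L: np.ndarray
    w: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def project_rows_to_simplex(V: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of V onto the probability simplex."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n, d = V.shape
    U = -np.sort(-V, axis=1)
    css = np.cumsum(U, axis=1)
    j = np.arange(1, d + 1)
    cond = U - (css - 1.0) / j > 0
    rho = cond.shape[1] - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = (css[np.arange(n), rho] - 1.0) / (rho + 1)
    return np.maximum(V - theta[:, None], 0.0)


def kernel_similarity_inner(bank: KernelBank, S: np.ndarray) -> np.ndarray:
    """<K_l, S> = sum_ij K_l(i, j) S_ij for every kernel in the bank."""
    return np.einsum("lij,ij->l", bank.kernels, S)


def objective(S: np.ndarray, L: np.ndarray, w: np.ndarray, bank: KernelBank,
              beta: float, gamma: float, rho: float) -> float:
    inner = kernel_similarity_inner(bank, S)
    fit_term = -float(w @ inner)
    reg_term = beta * float(np.sum(S * S))
    LLt = L @ L.T
    lap_term = gamma * (float(np.trace(L.T @ L)) - float(np.sum(S * LLt)))
    wpos = w[w > 0]
    ent_term = rho * float(np.sum(wpos * np.log(wpos)))
    return fit_term + reg_term + lap_term + ent_term


def update_L(S: np.ndarray, c: int) -> np.ndarray:
    """Bottom-c eigenvectors of the graph Laplacian of the symmetrized S."""
    n = S.shape[0]
    Ls = np.eye(n) - (S + S.T) / 2.0
    _, vecs = eigh(Ls, subset_by_index=[0, c - 1])
    return vecs


def update_w(S: np.ndarray, bank: KernelBank, rho: float) -> np.ndarray:
    """Entropic closed form w_l ∝ exp(<K_l, S> / rho) on the simplex."""
    g = kernel_similarity_inner(bank, S) / rho
    g -= g.max()
    w = np.exp(g)
    return w / w.sum()


def update_S(L: np.ndarray, w: np.ndarray, bank: KernelBank,
             beta: float, gamma: float) -> np.ndarray:
    """Row-wise simplex projection solving the S block exactly."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    A = np.einsum("l,lij->ij", w, bank.kernels) + gamma * (L @ L.T)
    return project_rows_to_simplex(A / (2.0 * beta))


def diffuse(S: np.ndarray, knn: int, steps: int) -> np.ndarray:
    """KNN-truncated graph diffusion of S; steps = 0 is the identity."""
    n = S.shape[0]
    if knn >= n:
        raise ValueError(f"diffusion knn={knn} must be < n={n}")
    if steps == 0:
        return S
    # stable argsort so equal similarities truncate deterministically
    order = np.argsort(-S, axis=1, kind="stable")
    T = np.zeros_like(S)
    rows = np.repeat(np.arange(n), knn)
    cols = order[:, :knn].ravel()
    T[rows, cols] = S[rows, cols]
    rs = T.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    T = T / rs
    out = S
    for _ in range(steps):
        out = T @ out @ T.T
    out = (out + out.T) / 2.0
    rs = out.sum(axis=1, keepdims=True)
    zero = rs[:, 0] == 0
    if zero.any():
        out[zero] = 1.0 / n
        rs = out.sum(axis=1, keepdims=True)
    return out / rs


def initial_similarity(bank: KernelBank) -> np.ndarray:
    """Row-normalized uniform average of the bank's normalized kernels."""
    S0 = bank.kernels.mean(axis=0)
    return S0 / S0.sum(axis=1, keepdims=True)


def fit_simlr(bank: KernelBank, config: SimlrConfig, callback=None) -> SimlrState:
    """Alternate exact block updates of L, w and S until convergence.

    ``callback(it, S, L, w)``, when given, is invoked after every full
    update cycle (e.g. to monitor constraint satisfaction).
    """
    n = bank.n
    if config.c >= n:
        raise ValueError(f"c={config.c} must be < n={n}")
    S = initial_similarity(bank)
    m = bank.m
    w = np.full(m, 1.0 / m)
    # totally symmetric input (e.g. all subjects identical): every kernel is
    # a constant matrix and carries no information.  Alternating updates
    # would then break the symmetry arbitrarily (the bottom eigenspace of
    # the uniform Laplacian is degenerate), so return the maximum-entropy
    # uniform similarity instead of solver-determined spurious structure.
    if float(np.ptp(bank.kernels)) <= 1e-12 * max(float(np.abs(bank.kernels).max()), 1.0):
        warnings.warn(
            "kernel bank is constant (totally symmetric input); "
            "returning the uniform similarity",
            RuntimeWarning, stacklevel=2,
        )
        S = np.full((n, n), 1.0 / n)
        L = update_L(S, config.c)
        F = objective(S, L, w, bank, config.beta, config.gamma, config.rho)
        return SimlrState(S=S, L=L, w=w, objective_trace=[F],
                          converged=True, n_iter=0)
    L = update_L(S, config.c)
    trace = [objective(S, L, w, bank, config.beta, config.gamma, config.rho)]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        L = update_L(S, config.c)
        w = update_w(S, bank, config.rho)
        S = update_S(L, w, bank, config.beta, config.gamma)
        if config.diffusion_steps > 0:
            S = diffuse(S, config.diffusion_knn, config.diffusion_steps)
        F = objective(S, L, w, bank, config.beta, config.gamma, config.rho)
        trace.append(F)
        if callback is not None:
            callback(it, S, L, w)
        if abs(trace[-1] - trace[-2]) <= config.tol * max(abs(trace[-2]), 1e-300):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"similarity learning did not converge in {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimlrState(S=S, L=L, w=w, objective_trace=trace,
                      converged=converged, n_iter=it)


class SIMLR(BaseEstimator, ClusterMixin):
    """Multi-kernel similarity learning and spectral-latent clustering.

    Builds a bank of adaptive-bandwidth Gaussian kernels over a (sigma, k)
    grid from the feature matrix, learns the similarity S / latent L /
    kernel weights w by alternating optimization, and clusters the rows of
    L with k-means.

    Parameters
    ----------
    n_clusters : int, default 4
        Number of clusters c (also the latent dimensionality).
    sigma_grid, k_grid : sequences
        Kernel hyperparameter grid; the defaults enumerate 21 kernels.
    beta, gamma, rho : float
        Weights of the Frobenius regularizer, Laplacian term and kernel-
        weight entropy.
    diffusion_steps, diffusion_knn :
        Graph-diffusion settings; ``diffusion_knn=None`` uses the median of
        ``k_grid``; ``diffusion_steps=0`` disables diffusion (and restores
        the monotone-objective guarantee).
    clamp_neighbors : bool, default True
        Shrink grid k values exceeding n - 1 to n - 1 (warns); otherwise
        such values raise.

    Attributes
    ----------
    similarity_ : ndarray of shape (n, n)
        Learned row-stochastic similarity.
    latent_ : ndarray of shape (n, n_clusters)
        Orthonormal spectral latent matrix.
    kernel_weights_ : ndarray of shape (m,)
        Learned simplex weights over the kernel bank.
    labels_ : ndarray of shape (n,)
        K-means cluster assignment of the latent rows.
    objective_trace_ : list of float
        Objective value per optimization cycle.
    """

    def __init__(self, n_clusters: int = 4, *, sigma_grid=DEFAULT_SIGMA_GRID,
                 k_grid=DEFAULT_K_GRID, beta: float = 0.8, gamma: float = 1.0,
                 rho: float = 1.0, diffusion_steps: int = 1,
                 diffusion_knn: int | None = None, max_iter: int = 30,
                 tol: float = 1e-6, kmeans_restarts: int = 50,
                 clamp_neighbors: bool = True, random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.sigma_grid = sigma_grid
        self.k_grid = k_grid
        self.beta = beta
        self.gamma = gamma
        self.rho = rho
        self.diffusion_steps = diffusion_steps
        self.diffusion_knn = diffusion_knn
        self.max_iter = max_iter
        self.tol = tol
        self.kmeans_restarts = kmeans_restarts
        self.clamp_neighbors = clamp_neighbors
        self.random_state = random_state

    def _effective_k_grid(self, n: int) -> list[int]:
        ks = []
        clamped = False
        for k in self.k_grid:
            if k >= n:
                if not self.clamp_neighbors:
                    raise ValueError(f"k_neighbors={k} must be < n={n}")
                clamped = True
                k = n - 1
            ks.append(int(k))
        ks = sorted(set(ks))
        if clamped:
            warnings.warn(
                f"neighbor counts clamped to n - 1 = {n - 1}",
                RuntimeWarning, stacklevel=3,
            )
        return ks

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n = X.shape[0]
        if self.n_clusters >= n:
            raise ValueError(f"n_clusters={self.n_clusters} must be < n={n}")
        k_grid = self._effective_k_grid(n)
        bank = build_kernel_bank(X, sigma_grid=self.sigma_grid, k_grid=k_grid)
        knn = self.diffusion_knn
        if knn is None:
            knn = int(np.median(k_grid))
        knn = min(int(knn), n - 1)
        config = SimlrConfig(
            c=self.n_clusters, beta=self.beta, gamma=self.gamma, rho=self.rho,
            max_iter=self.max_iter, tol=self.tol, diffusion_knn=knn,
            diffusion_steps=self.diffusion_steps,
            seed=self.random_state if self.random_state is not None else 0,
        )
        state = fit_simlr(bank, config)
        self.kernel_params_ = bank.params
        self.similarity_ = state.S
        self.latent_ = state.L
        self.kernel_weights_ = state.w
        self.objective_trace_ = state.objective_trace
        self.converged_ = state.converged
        self.n_iter_ = state.n_iter
        km = KMeans(n_clusters=self.n_clusters, n_init=self.kmeans_restarts,
                    random_state=self.random_state)
        self.labels_ = km.fit_predict(state.L)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
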