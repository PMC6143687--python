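"""Diffusion maps on single-cell data, built from first principles.

The construction follows the anisotropic diffusion-map recipe used
throughout single-cell trajectory inference:

1. a k-nearest-neighbour graph over cells (Euclidean distance on the
   transformed analysis markers), symmetrized by union;
2. a Gaussian kernel ``K_ij = exp(-d_ij^2 / (2 sigma^2))`` truncated outside
   the graph, with a single global bandwidth ``sigma`` (median distance to
   the ``k_scale``-th neighbour by default);
3. density normalization ``W_ij = K_ij / (q_i^alpha q_j^alpha)`` with
   ``q_i = sum_j K_ij``; ``alpha = 1`` removes sampling-density effects, so
   uneven cell numbers per time-point do not distort the geometry;
4. the Markov transition operator ``P = D^-1 W`` (``D_i = sum_j W_ij``),
   diagonalized through its symmetric conjugate
   ``S = D^1/2 P D^-1/2``, which shares eigenvalues with ``P``.

Eigenvectors are mapped back as ``psi = D^-1/2 v``; the trivial constant
eigenvector (eigenvalue 1) is verified and excluded, and the remaining
diffusion components DC1..DCm — the candidate pseudo-time axes — are
returned with unit Euclidean norm and a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

import pandas as pd

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    IsolatedPointError,
)
from .io_cytometry import EventTable

DEFAULT_K_SCALE = 15


@dataclass
class DiffusionParams:
    """Parameters of the diffusion-map construction.

    ``sigma="auto"`` estimates a global bandwidth as the median distance to
    the ``k_scale``-th nearest neighbour. ``alpha`` is the density
    normalization exponent in [0, 1] (1 = anisotropic, density-free).
    """

    n_components: int = 20
    k_neighbors: int = 100
    sigma: float | str = "auto"
    alpha: float = 1.0
    zero_diagonal: bool = True
    k_scale: int = DEFAULT_K_SCALE
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.sigma != "auto" and not self.sigma > 0:
            raise ValueError("sigma must be 'auto' or a positive number")


@dataclass
class KnnGraph:
    """Union-symmetrized kNN edge list with per-cell sorted NN distances."""

    n: int
    rows: np.ndarray       # edge sources, includes both (i,j) and (j,i)
    cols: np.ndarray
    dists: np.ndarray
    nn_dists: np.ndarray   # (n, k) distances to the k nearest, ascending

    @property
    def k(self) -> int:
        return self.nn_dists.shape[1]


@dataclass
class DiffusionMap:
    """Eigenvalues and diffusion-component coordinates of one cell set."""

    eigenvalues: np.ndarray          # descending, trivial lambda_0 excluded
    components: np.ndarray           # (n_cells, m); DC i = components[:, i-1]
    params: dict
    cell_index: pd.DataFrame         # provenance rows (patient, timepoint, ...)

    @property
    def n_cells(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def dc(self, index: int) -> np.ndarray:
        """1-based diffusion-component accessor (DC1 = leading)."""
        if not 1 <= index <= self.n_components:
            raise IndexError(f"DC index {index} out of range")
        return self.components[:, index - 1]


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def pairwise_knn(events_or_matrix, k: int) -> KnnGraph:
    """k-nearest-neighbour distances, symmetrized by union.

    Accepts an :class:`EventTable` (uses its intensity matrix) or a plain
    array. Distances are Euclidean; duplicate points yield zero-distance
    edges, which are retained.
    """
    X = (events_or_matrix.intensities
         if isinstance(events_or_matrix, EventTable) else
         np.asarray(events_or_matrix, dtype=np.float64))
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be < number of cells ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto")
    nn.fit(X)
    dist, idx = nn.kneighbors(X)
    # remove each query from its own neighbour list; with duplicate points
    # the self entry is not necessarily in column 0, so locate it (rows
    # without a self entry drop their most distant neighbour instead)
    n_rows, kk = idx.shape
    rows_idx = np.arange(n_rows)
    self_pos = np.argmax(idx == rows_idx[:, None], axis=1)
    has_self = idx[rows_idx, self_pos] == rows_idx
    drop = np.where(has_self, self_pos, kk - 1)
    keep_mask = np.ones((n_rows, kk), dtype=bool)
    keep_mask[rows_idx, drop] = False
    idx = idx[keep_mask].reshape(n_rows, k)
    dist = dist[keep_mask].reshape(n_rows, k)

    src = np.repeat(np.arange(n), k)
    dst = idx.ravel()
    d = dist.ravel()
    rows = np.concatenate([src, dst])
    cols = np.concatenate([dst, src])
    dd = np.concatenate([d, d])
    order = np.lexsort((cols, rows))
    rows, cols, dd = rows[order], cols[order], dd[order]
    keep = np.ones(len(rows), dtype=bool)
    keep[1:] = (rows[1:] != rows[:-1]) | (cols[1:] != cols[:-1])
    return KnnGraph(n, rows[keep], cols[keep], dd[keep], dist)


def estimate_sigma(knn: KnnGraph, k_scale: int = DEFAULT_K_SCALE) -> float:
    """Global kernel bandwidth: median distance to the k_scale-th neighbour."""
    if k_scale < 1 or k_scale > knn.k:
        raise ValueError(
            f"k_scale ({k_scale}) must be in [1, {knn.k}] for this graph")
    sigma = float(np.median(knn.nn_dists[:, k_scale - 1]))
    if sigma <= 0:
        raise DegenerateInputError(
            "estimated sigma is 0 (coincident points); supply sigma explicitly")
    return sigma


def kernel_matrix(knn: KnnGraph, sigma: float,
                  zero_diagonal: bool = True) -> sp.csr_matrix:
    """Sparse symmetric Gaussian kernel on the kNN graph."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    vals = np.exp(-knn.dists ** 2 / (2.0 * sigma ** 2))
    K = sp.csr_matrix((vals, (knn.rows, knn.cols)), shape=(knn.n, knn.n))
    if not zero_diagonal:
        K = K + sp.identity(knn.n, format="csr")
    return K


def density_normalized_transition(K: sp.spmatrix, alpha: float = 1.0
                                  ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Anisotropic normalization and row-stochastic transition operator.

    Returns ``(P, D)`` where ``P = D^-1 W``, ``W = K / (q_i^a q_j^a)`` and
    ``D`` are the row sums of ``W`` (the stationary weights up to scale).
    """
    K = K.tocsr()
    q = np.asarray(K.sum(axis=1)).ravel()
    isolated = np.flatnonzero(q == 0)
    if isolated.size:
        raise IsolatedPointError(isolated)
    if alpha != 0.0:
        inv_qa = q ** (-alpha)
        Dq = sp.diags(inv_qa)
        W = Dq @ K @ Dq
    else:
        W = K.copy()
    D = np.asarray(W.sum(axis=1)).ravel()
    P = sp.diags(1.0 / D) @ W
    return P.tocsr(), D


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|entry| coordinate is > 0."""
    out = components.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            out[:, j] = -col
    return out


def spectral_decompose(P: sp.spmatrix, weights: np.ndarray, m: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Top eigenpairs of the transition operator via its symmetric conjugate.

    Solves ``S = D^1/2 P D^-1/2`` (symmetric, same spectrum as ``P``),
    maps eigenvectors back as ``psi = D^-1/2 v``, verifies that the leading
    eigenvector is the constant one (coefficient of variation < 1e-6) and
    drops it. Returns ``(eigenvalues, psi)`` with eigenvalues descending,
    ``psi`` columns unit-norm with a fixed sign convention.
    """
    n = P.shape[0]
    if not 1 <= m < n - 1:
        raise ValueError(f"m ({m}) must satisfy 1 <= m < n-1 ({n - 1})")
    d_sqrt = np.sqrt(weights)
    S = sp.diags(d_sqrt) @ P @ sp.diags(1.0 / d_sqrt)
    S = (S + S.T) * 0.5  # symmetrize away round-off
    v0 = np.full(n, 1.0 / np.sqrt(n))
    evals, evecs = eigsh(S, k=m + 1, which="LA", v0=v0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # The eigenvector of S at eigenvalue 1 is D^1/2 * const. If that
    # eigenvalue is degenerate (disconnected graph) ARPACK returns an
    # arbitrary basis of the eigenspace; rotate it so the constant vector
    # comes first before checking.
    top = np.flatnonzero(evals > evals[0] - 1e-10)
    if top.size > 1:
        V = evecs[:, top]
        c = d_sqrt / np.linalg.norm(d_sqrt)
        coeff = V.T @ c
        proj = V @ coeff
        if np.linalg.norm(proj) > 1e-8:
            basis = [proj / np.linalg.norm(proj)]
            for j in range(V.shape[1]):
                w = V[:, j]
                for b in basis:
                    w = w - (b @ w) * b
                nw = np.linalg.norm(w)
                if nw > 1e-8 and len(basis) < V.shape[1]:
                    basis.append(w / nw)
            if len(basis) == V.shape[1]:
                evecs[:, top] = np.column_stack(basis)

    psi = evecs / d_sqrt[:, None]
    psi0 = psi[:, 0]
    cv = np.std(psi0) / max(abs(np.mean(psi0)), np.finfo(float).tiny)
    if cv > 1e-6:
        raise DegenerateInputError(
            f"leading eigenvector is not constant (CV={cv:.2e}); "
            "the kernel graph is numerically degenerate")
    lam0 = evals[0]
    if abs(lam0 - 1.0) > 1e-8:
        raise DegenerateInputError(
            f"leading eigenvalue {lam0} deviates from 1 beyond tolerance")

    evals, psi = evals[1:], psi[:, 1:]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    return evals, _fix_signs(psi)


def compute_diffusion_map(events: EventTable,
                          params: DiffusionParams | None = None) -> DiffusionMap:
    """Full pipeline: kNN -> sigma -> kernel -> transition -> spectrum."""
    params = params or DiffusionParams()
    n = events.n_cells
    if n < params.n_components + 2:
        raise InsufficientDataError(
            f"need >= {params.n_components + 2} cells for "
            f"{params.n_components} components, got {n}")
    k = min(params.k_neighbors, n - 1)
    knn = pairwise_knn(events, k)
    if params.sigma == "auto":
        sigma = estimate_sigma(knn, k_scale=min(params.k_scale, k))
    else:
        sigma = float(params.sigma)
    K = kernel_matrix(knn, sigma, zero_diagonal=params.zero_diagonal)
    P, D = density_normalized_transition(K, alpha=params.alpha)
    evals, psi = spectral_decompose(P, D, params.n_components)
    resolved = {
        "n_components": params.n_components,
        "k_neighbors": k,
        "sigma": sigma,
        "alpha": params.alpha,
        "zero_diagonal": params.zero_diagonal,
        "k_scale": params.k_scale,
        "seed": params.seed,
    }
    return DiffusionMap(evals, psi, resolved, events.annotations.copy())


def align_signs(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Flip columns of ``other`` to best correlate with ``reference``.

    The eigenvector sign is mathematically arbitrary; comparisons between
    runs must align signs first.
    """
    out = other.copy()
    for j in range(out.shape[1]):
        if np.dot(reference[:, j], out[:, j]) < 0:
            out[:, j] = -out[:, j]
    return out
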