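"""Straightforward dense diffusion-map implementation used as a test oracle.

Kept deliberately naive and independent of the package's sparse code path:
full pairwise distances, dense Gaussian kernel, dense symmetric
eigendecomposition via LAPACK.
"""

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import distance_matrix


def dense_diffusion_map(X, sigma, m, alpha=1.0, zero_diagonal=True):
    """Return (eigenvalues, components) exactly as the package defines them.

    Top ``m`` non-trivial eigenpairs of the density-normalized transition
    operator; components unit-norm, trivial constant eigenvector dropped.
    Signs are arbitrary — align before comparing.
    """
    D = distance_matrix(X, X)
    K = np.exp(-D ** 2 / (2.0 * sigma ** 2))
    if zero_diagonal:
        np.fill_diagonal(K, 0.0)
    q = K.sum(axis=1)
    W = K / np.outer(q ** alpha, q ** alpha)
    d = W.sum(axis=1)
    S = W / np.sqrt(np.outer(d, d))      # = D^1/2 P D^-1/2
    evals, evecs = eigh(S)
    order = np.argsort(evals)[::-1][: m + 1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(d)[:, None]
    assert np.std(psi[:, 0]) / abs(np.mean(psi[:, 0])) < 1e-6
    psi = psi[:, 1:]
    psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
    return evals[1:], psi


def brute_force_transition(dists, sigma, alpha):
    """Hand-computable transition matrix for tiny graphs (dense input)."""
    K = np.exp(-np.asarray(dists, float) ** 2 / (2.0 * sigma ** 2))
    np.fill_diagonal(K, 0.0)
    q = K.sum(axis=1)
    W = K / np.outer(q ** alpha, q ** alpha)
    return W / W.sum(axis=1, keepdims=True)
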