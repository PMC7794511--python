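"""Exact Gaussian-process machinery for the per-site spatial term.

The spatial random effect at each site is a zero-mean GP over the raw
(unscaled) cell-centroid coordinates with an exponentiated-quadratic kernel

    k(d) = sd^2 * exp(-d^2 / (2 * lengthscale^2)),

evaluated with the full dense covariance (no low-rank approximation). The
sampler works in a whitened parameterization ``gp = L z`` with
``L = sd * chol(R + jitter I)`` and ``z ~ N(0, I)``, so the correlation
Cholesky and its lengthscale derivative are the primitives here.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = ["gp_covariance", "safe_cholesky", "chol_diff", "squared_distances"]

JITTER = 1e-8
MAX_JITTER = 1e-4


def squared_distances(coords: np.ndarray) -> np.ndarray:
    """Dense matrix of squared Euclidean distances between rows of coords."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def gp_covariance(
    coords: np.ndarray, gp_sd: float, gp_lengthscale: float, jitter: float = JITTER
) -> np.ndarray:
    """Kernel matrix over cell centroids, with diagonal jitter ``jitter*sd^2``."""
    if gp_sd < 0:
        raise ValueError("gp_sd must be >= 0")
    if gp_lengthscale <= 0:
        raise ValueError("gp_lengthscale must be > 0")
    d2 = squared_distances(coords)
    R = np.exp(-0.5 * d2 / gp_lengthscale**2)
    return gp_sd**2 * (R + jitter * np.eye(len(R)))


def safe_cholesky(A: np.ndarray, label: str = "matrix") -> np.ndarray:
    """Lower Cholesky with jitter escalation (x10 per retry up to 1e-4).

    ``A`` is assumed to already carry the baseline jitter; escalation adds
    multiples of the mean diagonal. Raises with the label and the last
    jitter tried if the matrix never factorizes.
    """
    jitter = 0.0
    diag_scale = float(np.mean(np.diag(A))) or 1.0
    for _ in range(6):
        try:
            return cholesky(A + jitter * diag_scale * np.eye(len(A)), lower=True)
        except np.linalg.LinAlgError:
            jitter = JITTER if jitter == 0.0 else jitter * 10.0
            if jitter > MAX_JITTER:
                break
    raise np.linalg.LinAlgError(
        f"covariance for {label} not positive definite (last jitter {jitter:.1e})"
    )


def chol_diff(L: np.ndarray, dA: np.ndarray) -> np.ndarray:
    """Forward-mode derivative of the Cholesky factor.

    Given ``A = L L^T`` and a perturbation ``dA``, returns ``dL`` via
    ``dL = L Phi(L^{-1} dA L^{-T})`` where Phi keeps the strict lower
    triangle and halves the diagonal.
    """
    M = solve_triangular(L, dA, lower=True)
    M = solve_triangular(L, M.T, lower=True).T
    Phi = np.tril(M)
    np.fill_diagonal(Phi, 0.5 * np.diag(M))
    return L @ Phi
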