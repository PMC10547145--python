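"""Shared multivariate-normal likelihood machinery.

Pedigree covariance matrices are block-diagonal across families, so every
likelihood evaluation factors into small per-family Cholesky solves; the
fixed effects β are profiled out by generalized least squares at each
covariance evaluation.  All fitters route through this module; the public
``*_loglik`` functions in :mod:`famgxe.polygenic` and :mod:`famgxe.gxe`
evaluate the same density densely and serve as the externally visible
(and independently testable) definition.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["detect_blocks", "gls_profile_loglik", "dense_mvn_loglik"]

_LN2PI = float(np.log(2.0 * np.pi))


def detect_blocks(K: np.ndarray, tol: float = 0.0) -> list[np.ndarray]:
    """Connected components of the nonzero pattern of K.

    Families are mutually unrelated, so the relationship matrix of a
    multi-family sample is block-diagonal (up to row order); exploiting
    this turns one n³ factorization into many small ones.
    """
    mask = np.abs(K) > tol
    n_comp, labels = connected_components(csr_matrix(mask), directed=False)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


def gls_profile_loglik(
    y: np.ndarray,
    X: np.ndarray,
    cov_of_block,
    blocks: list[np.ndarray],
) -> tuple[float, np.ndarray, float]:
    """Maximized-over-β Gaussian log-likelihood for a block covariance.

    ``cov_of_block(idx)`` must return the covariance sub-matrix for the
    individuals in ``idx``.  Returns ``(loglik, beta_gls, quad)`` where
    ``quad = r'Σ⁻¹r`` at the GLS β.  Raises ``LinAlgError`` if any block
    is not positive definite.
    """
    n, p = X.shape
    A = np.zeros((p, p))
    c = np.zeros(p)
    yy = 0.0
    logdet = 0.0
    for idx in blocks:
        C = cov_of_block(idx)
        L = cho_factor(C, lower=True, check_finite=False)
        logdet += 2.0 * np.sum(np.log(np.diag(L[0])))
        Xb, yb = X[idx], y[idx]
        CiX = cho_solve(L, Xb, check_finite=False)
        Ciy = cho_solve(L, yb, check_finite=False)
        A += Xb.T @ CiX
        c += Xb.T @ Ciy
        yy += yb @ Ciy
    beta = np.linalg.solve(A, c)
    quad = yy - 2.0 * beta @ c + beta @ A @ beta
    loglik = -0.5 * (n * _LN2PI + logdet + quad)
    return loglik, beta, quad


def dense_mvn_loglik(r: np.ndarray, sigma: np.ndarray) -> float:
    """Log-density of MVN(0, Σ) at residual vector r via one Cholesky."""
    try:
        L = cho_factor(sigma, lower=True, check_finite=False)
    except LinAlgError as exc:
        raise LinAlgError("covariance not positive definite") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L[0])))
    quad = r @ cho_solve(L, r, check_finite=False)
    return -0.5 * (len(r) * _LN2PI + logdet + quad)
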