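"""BLUP genetic values and the genetically corrected environment.

An environment index like years of education is itself heritable, so a
genotype-by-environment test against the raw index partly contrasts
genotypes against their own genetic propensity for the environment.  To
isolate the environmental exposure we predict each individual's additive
genetic value for the index by best linear unbiased prediction (BLUP)
under the index's own polygenic fit and subtract it:

    ĝ = σ̂g² K Σ̂⁻¹ (q − Xβ̂),   q_corrected = q − ĝ,

with Σ̂ = K σ̂g² + I σ̂e².  BLUP shrinks toward the fixed-effect mean and
borrows information across relatives through K; the corrected index
reflects primarily environmental variation and is the focal environment
handed to the interaction model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .pedigree import KinshipMatrix
from .polygenic import PolygenicFit

__all__ = ["CorrectedEnvironment", "blup_genetic_values", "correct_environment"]


@dataclass
class CorrectedEnvironment:
    """Raw index, predicted genetic values, and their difference."""

    q_raw: np.ndarray
    g_hat: np.ndarray
    q_corrected: np.ndarray
    fit: PolygenicFit

    def __post_init__(self) -> None:
        if not np.allclose(self.q_corrected + self.g_hat, self.q_raw):
            raise ValueError("q_corrected + g_hat must equal q_raw")


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def blup_genetic_values(fit: PolygenicFit, q, X=None, K=None) -> np.ndarray:
    """Predicted additive genetic values ĝ = σ̂g² K Σ̂⁻¹ (q − Xβ̂).

    Equivalent to the genetic-effect solution of Henderson's mixed-model
    equations at the plugged-in variance components.  For K = I this
    reduces to a uniform shrink ĥ²·(q − Xβ̂).
    """
    q = np.asarray(q, dtype=float)
    n = len(q)
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    Km = _as_matrix(K)
    if Km.shape != (n, n) or X.shape[0] != n:
        raise ValueError("dimension mismatch between q, X and K")
    if fit.sigma_g2 == 0:
        return np.zeros(n)
    r = q - X @ np.atleast_1d(fit.beta_hat)
    sigma = Km * fit.sigma_g2 + np.eye(n) * fit.sigma_e2
    L = cho_factor(sigma, lower=True, check_finite=False)
    return fit.sigma_g2 * (Km @ cho_solve(L, r, check_finite=False))


def correct_environment(q, fit: PolygenicFit, X=None, K=None) -> CorrectedEnvironment:
    """Subtract BLUP genetic values from a heritable environment index."""
    q = np.asarray(q, dtype=float)
    g_hat = blup_genetic_values(fit, q, X, K)
    return CorrectedEnvironment(
        q_raw=q, g_hat=g_hat, q_corrected=q - g_hat, fit=fit
    )
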