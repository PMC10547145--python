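"""Baseline polygenic variance-components model.

The phenotype of n related individuals is modeled as

    y = Xβ + g + e,   Cov(y) = Σ = K σg² + I σe²,

with K the additive relationship matrix (2Φ convention), σg² the additive
genetic variance and σe² the residual environmental variance.  Narrow-sense
heritability is h² = σg² / (σg² + σe²).  The model is fit by full maximum
likelihood: β is profiled out by generalized least squares, the total
variance σp² = σg² + σe² is profiled in closed form, and the remaining
one-dimensional likelihood in h² is maximized on [0, 1] with the boundary
h² = 0 always evaluated explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError
from scipy.optimize import minimize_scalar

from ._likelihood import detect_blocks, dense_mvn_loglik, gls_profile_loglik
from .pedigree import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = ["PolygenicFit", "heritability", "polygenic_loglik", "fit_polygenic"]

_LN2PI = float(np.log(2.0 * np.pi))


def heritability(sigma_g2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability σg² / (σg² + σe²)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_g2 + sigma_e2
    if tot <= 0:
        raise ValueError("total variance must be positive")
    return sigma_g2 / tot


@dataclass
class PolygenicFit:
    """Maximum-likelihood fit of the polygenic model."""

    beta_hat: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    converged: bool
    n: int
    boundary: bool = False

    def summary_row(self) -> str:
        se = "unreliable" if np.isnan(self.se_h2) else f"{self.se_h2:.2f}"
        return f"{self.h2:.2f} ({se})"

    def to_record(self) -> dict:
        return {
            "beta": [float(b) for b in np.atleast_1d(self.beta_hat)],
            "sigma_g2": float(self.sigma_g2),
            "sigma_e2": float(self.sigma_e2),
            "h2": float(self.h2),
            "se_h2": None if np.isnan(self.se_h2) else float(self.se_h2),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n": int(self.n),
        }


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def polygenic_loglik(sigma_g2, sigma_e2, beta, y, X, K) -> float:
    """Exact multivariate-normal log-likelihood at given parameter values.

    Evaluated densely through one Cholesky of Σ = K σg² + I σe²; raises if
    Σ is numerically singular.
    """
    if sigma_g2 < 0 or sigma_e2 < 0 or sigma_g2 + sigma_e2 == 0:
        raise ValueError("need sigma_g2, sigma_e2 >= 0 and not both zero")
    Km = _as_matrix(K)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    r = y - X @ np.atleast_1d(np.asarray(beta, dtype=float))
    sigma = Km * sigma_g2 + np.eye(len(y)) * sigma_e2
    return dense_mvn_loglik(r, sigma)


def _h2_profile(h2: float, y, X, K, blocks, eyes):
    """Profile log-likelihood over β and total variance at fixed h²."""
    def cov(idx):
        i = len(idx)
        return h2 * K[np.ix_(idx, idx)] + (1.0 - h2) * eyes[i]

    n = len(y)
    loglik_unit, beta, quad = gls_profile_loglik(y, X, cov, blocks)
    sp2 = quad / n
    # rescale the unit-variance likelihood to the profiled total variance
    loglik = loglik_unit + 0.5 * quad - 0.5 * n * (np.log(sp2) + 1.0)
    return loglik, beta, sp2


def fit_polygenic(y, X=None, K=None, min_n: int = 30) -> PolygenicFit:
    """Full-ML fit of Σ = K σg² + I σe² with GLS-profiled fixed effects.

    The likelihood is maximized exactly along the h² profile (β and the
    total variance are both profiled in closed form), with a coarse grid
    bracketing a bounded scalar search and the σg² = 0 boundary always
    evaluated as a candidate.  SE(h²) comes from the delta method applied
    to the numerically estimated observed information of
    (log σg², log σe²); boundary estimates carry ``se_h2 = nan``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < min_n:
        raise ValueError(f"insufficient sample: n = {n} < {min_n}")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    Km = _as_matrix(K)
    if Km.shape != (n, n):
        raise ValueError("kinship matrix does not match phenotype length")
    blocks = detect_blocks(Km)
    eyes = {len(ix): np.eye(len(ix)) for ix in blocks}
    if all(len(ix) == 1 for ix in blocks) and np.allclose(np.diag(Km), 1.0):
        logger.warning(
            "K is the identity: sigma_g2 and sigma_e2 are identifiable only "
            "as a sum; h2 estimate is arbitrary along the profile"
        )

    def nll(h2: float) -> float:
        try:
            return -_h2_profile(h2, y, X, Km, blocks, eyes)[0]
        except LinAlgError:
            return np.inf

    grid = np.linspace(0.0, 0.99, 34)
    grid_vals = np.array([nll(h) for h in grid])
    j = int(np.argmin(grid_vals))
    lo = grid[max(j - 1, 0)]
    hi = min(grid[min(j + 1, len(grid) - 1)], 1.0 - 1e-9)
    opt = minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    candidates = [(float(opt.x), -float(opt.fun)), (0.0, -nll(0.0))]
    h2_hat, loglik = max(candidates, key=lambda t: t[1])
    _, beta, sp2 = _h2_profile(h2_hat, y, X, Km, blocks, eyes)
    sg2, se2 = h2_hat * sp2, (1.0 - h2_hat) * sp2
    boundary = h2_hat < 1e-6 or h2_hat > 1.0 - 1e-5

    se_h2 = np.nan
    if not boundary:
        se_h2 = _delta_se_h2(sg2, se2, y, X, Km, blocks, eyes)
    return PolygenicFit(
        beta_hat=beta,
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        h2=float(h2_hat),
        se_h2=float(se_h2),
        loglik=float(loglik),
        converged=bool(opt.success),
        n=n,
        boundary=boundary,
    )


def _loglik_uv(u: float, v: float, y, X, K, blocks, eyes) -> float:
    """β-profiled log-likelihood in (u, v) = (log σg², log σe²)."""
    sg2, se2 = np.exp(u), np.exp(v)

    def cov(idx):
        return sg2 * K[np.ix_(idx, idx)] + se2 * eyes[len(idx)]

    return gls_profile_loglik(y, X, cov, blocks)[0]


def _delta_se_h2(sg2, se2, y, X, K, blocks, eyes, step: float = 1e-4) -> float:
    """Delta-method SE of h² from the observed information of (u, v)."""
    u0, v0 = np.log(sg2), np.log(se2)

    def f(u, v):
        return _loglik_uv(u, v, y, X, K, blocks, eyes)

    h = step
    try:
        f00 = f(u0, v0)
        d2u = (f(u0 + h, v0) - 2 * f00 + f(u0 - h, v0)) / h**2
        d2v = (f(u0, v0 + h) - 2 * f00 + f(u0, v0 - h)) / h**2
        duv = (
            f(u0 + h, v0 + h) - f(u0 + h, v0 - h) - f(u0 - h, v0 + h)
            + f(u0 - h, v0 - h)
        ) / (4 * h**2)
        info = -np.array([[d2u, duv], [duv, d2v]])
        cov = np.linalg.inv(info)
    except (LinAlgError, np.linalg.LinAlgError):
        return np.nan
    h2 = sg2 / (sg2 + se2)
    grad = np.array([h2 * (1 - h2), -h2 * (1 - h2)])
    var = grad @ cov @ grad
    return float(np.sqrt(var)) if var > 0 else np.nan
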