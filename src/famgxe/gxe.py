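"""Continuous-environment genotype-by-environment interaction model.

The polygenic model assumes the additive genetic variance is homogeneous
across environments and that the genetic correlation between any two
relatives' expressed polygenotypes is one.  This module relaxes both by
treating the genetic effects as a Gaussian stationary process indexed by a
continuous environment q (education years, an income score, ...):

    σg²(q)      = exp(αg + γg (q − q̄))           genetic variance function
    ρg(qi, qj)  = exp(−λg |qi − qj|)              genetic correlation function
    σe²(q)      = exp(αe + γe (q − q̄))           residual variance function

The phenotypic covariance becomes Σ = K ⊙ Ψ + Δ, where ⊙ is the Hadamard
(elementwise) product, Ψ collects the genetic variance/covariance function

    ψij = exp(αg + ½γg (qi + qj − 2q̄) − λg |qi − qj|),

and Δ = diag(σe²(qi)).  Setting γg = λg = γe = 0 recovers the polygenic
model with σg² = exp(αg), σe² = exp(αe); those three parameters are the
interaction hypotheses tested by :mod:`famgxe.inference`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError
from scipy.optimize import minimize

from ._likelihood import detect_blocks, dense_mvn_loglik, gls_profile_loglik
from .pedigree import KinshipMatrix
from .polygenic import PolygenicFit, fit_polygenic

logger = logging.getLogger(__name__)

__all__ = [
    "GxEParameters",
    "GxEFit",
    "EnvironmentIndex",
    "TESTABLE_PARAMS",
    "genetic_variance_at",
    "genetic_correlation_between",
    "residual_variance_at",
    "two_environment_gxe_variance",
    "assemble_covariance",
    "gxe_loglik",
    "fit_gxe",
]

#: interaction parameters that may be constrained to 0 in hypothesis tests
TESTABLE_PARAMS = ("gamma_g", "lambda_g", "gamma_e")
_PARAM_NAMES = ("alpha_g", "gamma_g", "lambda_g", "alpha_e", "gamma_e")
_EXP_GUARD = 80.0  # |log-variance| beyond this is treated as numerically invalid


@dataclass
class GxEParameters:
    """Variance/correlation-function parameters of the interaction model.

    ``alpha_g``/``alpha_e`` are log variances at the mean environment;
    ``gamma_g``/``gamma_e`` are log-variance slopes per environment unit;
    ``lambda_g`` >= 0 is the genetic-correlation decay rate per unit of
    environmental difference.  ``beta`` holds fixed-effect coefficients.
    """

    alpha_g: float = 0.0
    gamma_g: float = 0.0
    lambda_g: float = 0.0
    alpha_e: float = 0.0
    gamma_e: float = 0.0
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lambda_g < 0:
            raise ValueError("lambda_g must be non-negative")
        for name in _PARAM_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in _PARAM_NAMES])

    @classmethod
    def from_vector(cls, vec, beta=None) -> "GxEParameters":
        return cls(**dict(zip(_PARAM_NAMES, map(float, vec))), beta=beta)


@dataclass
class EnvironmentIndex:
    """Per-individual environment values and their analysis-sample mean."""

    q: np.ndarray
    q_bar: float | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if not np.isfinite(self.q).all():
            raise ValueError("environment values must be finite")
        if self.q_bar is None:
            self.q_bar = float(self.q.mean())

    @property
    def range(self) -> float:
        return float(self.q.max() - self.q.min())


def genetic_variance_at(alpha_g, gamma_g, q, q_bar):
    """Additive genetic variance exp(αg + γg (q − q̄)) at environment q."""
    return np.exp(alpha_g + gamma_g * (np.asarray(q, dtype=float) - q_bar))


def genetic_correlation_between(lambda_g, q_i, q_j):
    """Genetic correlation exp(−λg |qi − qj|) between two environments."""
    if lambda_g < 0:
        raise ValueError("lambda_g must be non-negative")
    return np.exp(-lambda_g * np.abs(np.asarray(q_i, dtype=float) - q_j))


def residual_variance_at(alpha_e, gamma_e, q, q_bar):
    """Residual environmental variance exp(αe + γe (q − q̄)) at q."""
    return np.exp(alpha_e + gamma_e * (np.asarray(q, dtype=float) - q_bar))


def two_environment_gxe_variance(sigma_g1_sq, sigma_g2_sq, rho_g) -> float:
    """GxE variance for a two-environment contrast.

    σ²gΔ = σg1² + σg2² − 2 ρg σg1 σg2; equals 2σg²(1 − ρg) for equal
    variances, and is zero iff the variances are equal and ρg = 1.
    """
    if sigma_g1_sq < 0 or sigma_g2_sq < 0:
        raise ValueError("variances must be non-negative")
    if not -1.0 <= rho_g <= 1.0:
        raise ValueError("rho_g must be in [-1, 1]")
    return float(
        sigma_g1_sq + sigma_g2_sq
        - 2.0 * rho_g * np.sqrt(sigma_g1_sq * sigma_g2_sq)
    )


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _psi(params: GxEParameters, q: np.ndarray, q_bar: float) -> np.ndarray:
    s = 0.5 * params.gamma_g * (q - q_bar)
    expo = params.alpha_g + s[:, None] + s[None, :] \
        - params.lambda_g * np.abs(q[:, None] - q[None, :])
    return np.exp(expo)


def assemble_covariance(K, params: GxEParameters, env: EnvironmentIndex) -> np.ndarray:
    """Phenotypic covariance Σ = K ⊙ Ψ + Δ for the interaction model."""
    Km = _as_matrix(K)
    q = env.q
    if Km.shape[0] != len(q):
        raise ValueError("kinship matrix does not match environment length")
    dg = params.alpha_g + params.gamma_g * (q - env.q_bar)
    de = params.alpha_e + params.gamma_e * (q - env.q_bar)
    if np.abs(dg).max() > _EXP_GUARD or np.abs(de).max() > _EXP_GUARD:
        raise FloatingPointError("variance function overflows; non-finite entries")
    sigma = Km * _psi(params, q, env.q_bar)
    sigma[np.diag_indices_from(sigma)] += np.exp(de)
    return sigma


def gxe_loglik(params: GxEParameters, y, X, K, env: EnvironmentIndex) -> float:
    """Exact MVN log-likelihood under Σ = K ⊙ Ψ + Δ at given parameters."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    beta = params.beta
    if beta is None:
        raise ValueError("params.beta must be set to evaluate the likelihood")
    r = y - X @ np.atleast_1d(np.asarray(beta, dtype=float))
    sigma = assemble_covariance(K, params, env)
    return dense_mvn_loglik(r, sigma)


@dataclass
class GxEFit:
    """ML fit of the interaction model under a set of zero constraints."""

    params: GxEParameters
    ses: dict[str, float]
    loglik: float
    constraints: frozenset = field(default_factory=frozenset)
    converged: bool = True
    n: int = 0

    def param(self, name: str) -> float:
        return float(getattr(self.params, name))

    def se(self, name: str) -> float:
        return float(self.ses.get(name, np.nan))

    def to_record(self) -> dict:
        return {
            "params": {p: self.param(p) for p in _PARAM_NAMES},
            "beta": [float(b) for b in np.atleast_1d(self.params.beta)],
            "ses": {
                k: (None if np.isnan(v) else float(v)) for k, v in self.ses.items()
            },
            "loglik": float(self.loglik),
            "constraints": sorted(self.constraints),
            "converged": bool(self.converged),
            "n": int(self.n),
        }


def _assemble_raw(K, vals: dict, q: np.ndarray, q_bar: float) -> np.ndarray:
    """Covariance assembly without parameter validation.

    Used by the optimizer and the observed-information stencil, which
    evaluates the smooth extension of the likelihood through λg = 0 (the
    correlation kernel is evaluable for small negative rates; positive
    definiteness is still enforced by the Cholesky downstream).
    """
    dg = vals["alpha_g"] + vals["gamma_g"] * (q - q_bar)
    de = vals["alpha_e"] + vals["gamma_e"] * (q - q_bar)
    if np.abs(dg).max() > _EXP_GUARD or np.abs(de).max() > _EXP_GUARD:
        raise FloatingPointError("variance function overflows")
    s = 0.5 * vals["gamma_g"] * (q - q_bar)
    expo = vals["alpha_g"] + s[:, None] + s[None, :] \
        - vals["lambda_g"] * np.abs(q[:, None] - q[None, :])
    sigma = K * np.exp(expo)
    sigma[np.diag_indices_from(sigma)] += np.exp(de)
    return sigma


def _block_loglik(vec, free, fixed, y, X, K, blocks, env):
    vals = dict(fixed)
    vals.update(zip(free, vec))
    q, q_bar = env.q, env.q_bar

    def cov(idx):
        return _assemble_raw(K[np.ix_(idx, idx)], vals, q[idx], q_bar)

    return gls_profile_loglik(y, X, cov, blocks)


def _safe_nll(vec, free, fixed, y, X, K, blocks, env) -> float:
    try:
        ll = _block_loglik(vec, free, fixed, y, X, K, blocks, env)[0]
    except (LinAlgError, FloatingPointError, ValueError):
        return 1e10
    return -ll if np.isfinite(ll) else 1e10


def _hessian(f, x0: np.ndarray, h: np.ndarray) -> np.ndarray:
    k = len(x0)
    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej)
                + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _numeric_ses(
    theta, free, fixed, y, X, K, blocks, env, bounds
) -> dict[str, float]:
    """SEs from the observed information (central-difference Hessian).

    The likelihood is evaluated through its smooth extension, so a λg
    estimate sitting on the λg = 0 boundary still gets a curvature-based
    SE (the stencil steps take the correlation kernel marginally above 1,
    which keeps the covariance positive definite for small steps).  If
    the stencil nevertheless leaves the positive-definite region, the
    offending parameter is excluded and reported with ``nan`` SE.
    """
    ses = {name: np.nan for name in free}
    names = list(free)
    th0 = np.asarray(theta, dtype=float)
    fixed_all = dict(fixed)

    bad = 1e9

    def make_f(sel_names):
        def f(v):
            return -_safe_nll(v, sel_names, fixed_all, y, X, K, blocks, env)
        return f

    while names:
        idx = [free.index(nm) for nm in names]
        x0 = th0[idx]
        h = 1e-4 * (1.0 + np.abs(x0))
        fixed_all = dict(fixed)
        fixed_all.update(
            (free[i], th0[i]) for i in range(len(free)) if i not in idx
        )
        evals: list[float] = []
        f_raw = make_f(names)

        def f(v):
            val = f_raw(v)
            evals.append(val)
            return val

        H = _hessian(f, x0, h)
        if all(v > -bad for v in evals):
            try:
                cov = np.linalg.inv(-H)
                diag = np.diag(cov)
                for name, v in zip(names, diag):
                    ses[name] = float(np.sqrt(v)) if v > 0 else np.nan
            except np.linalg.LinAlgError:
                pass
            return ses
        # stencil left the valid region: drop boundary parameters and retry
        boundary = [
            nm for nm in names
            if bounds[free.index(nm)][0] is not None
            and th0[free.index(nm)] - bounds[free.index(nm)][0] < 1e-8
        ]
        if not boundary:
            return ses
        names = [nm for nm in names if nm not in boundary]
    return ses


def fit_gxe(
    y,
    X=None,
    K=None,
    env: EnvironmentIndex | None = None,
    constraints=(),
    poly: PolygenicFit | None = None,
    cache: dict | None = None,
    min_n: int = 30,
    compute_ses: bool = True,
) -> GxEFit:
    """Maximum-likelihood fit of the interaction model.

    ``constraints`` names interaction parameters (among ``gamma_g``,
    ``lambda_g``, ``gamma_e``) held at exactly 0; β is profiled out by GLS
    at every covariance evaluation.  Optimization is warm-started from the
    polygenic fit (αg = ln σ̂g², αe = ln σ̂e², slopes 0).  Whenever λg is
    free, the λg = 0 constrained sub-model is fitted first (recursively)
    and both used as a second start and adopted outright if the boundary
    attains the maximum — this keeps nested log-likelihoods exactly
    monotone and makes the boundary point mass of the λg test exact.

    λg is bounded above by 50 / range(q): correlations below e⁻⁵⁰ are
    numerically zero and larger rates create likelihood plateaus.

    ``cache`` (optional dict) memoizes fits by constraint set so that a
    testing protocol sharing nested fits never refits the same model.
    """
    constraints = frozenset(constraints)
    invalid = constraints - set(TESTABLE_PARAMS)
    if invalid:
        raise ValueError(f"cannot constrain {sorted(invalid)}")
    if cache is not None and constraints in cache:
        return cache[constraints]

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
    if env is None or len(env.q) != n:
        raise ValueError("environment index must align with the phenotype")
    blocks = detect_blocks(Km)

    if poly is None:
        poly = fit_polygenic(y, X, Km, min_n=min_n)
    var_floor = 1e-6 * (poly.sigma_g2 + poly.sigma_e2)
    warm = {
        "alpha_g": float(np.log(max(poly.sigma_g2, var_floor))),
        "gamma_g": 0.0,
        "lambda_g": 0.0,
        "alpha_e": float(np.log(max(poly.sigma_e2, var_floor))),
        "gamma_e": 0.0,
    }

    q_range = env.range
    lam_hi = 50.0 / q_range if q_range > 0 else 0.0
    gam_hi = 50.0 / q_range if q_range > 0 else 1.0
    all_bounds = {
        "alpha_g": (-30.0, 30.0),
        "gamma_g": (-gam_hi, gam_hi),
        "lambda_g": (0.0, lam_hi),
        "alpha_e": (-30.0, 30.0),
        "gamma_e": (-gam_hi, gam_hi),
    }

    eff_constraints = set(constraints)
    if q_range == 0 and "lambda_g" not in eff_constraints:
        logger.warning("environment has zero range; lambda_g not identifiable")
        eff_constraints.add("lambda_g")
    free = [p for p in _PARAM_NAMES if p not in eff_constraints]
    fixed = {p: 0.0 for p in eff_constraints}
    bounds = [all_bounds[p] for p in free]

    sub: GxEFit | None = None
    if "lambda_g" in free:
        sub = fit_gxe(
            y, X, Km, env,
            constraints=constraints | {"lambda_g"},
            poly=poly, cache=cache, min_n=min_n, compute_ses=False,
        )

    starts = [np.array([warm[p] for p in free])]
    if sub is not None:
        v = sub.params.as_vector()
        sub_start = np.array([v[_PARAM_NAMES.index(p)] for p in free])
        starts.append(sub_start)
        # interior-λg start: both other starts sit on the λg = 0 boundary,
        # which can leave an interior maximum unexplored.  Scale so the
        # correlation at a typical environmental difference is ~0.6.
        q_sd = float(np.std(env.q))
        if q_sd > 0:
            lam0 = min(0.35 / q_sd, 0.5 * lam_hi)
            interior = sub_start.copy()
            interior[free.index("lambda_g")] = lam0
            starts.append(interior)

    best_theta, best_ll, converged = None, -np.inf, False
    for s0 in starts:
        res = minimize(
            _safe_nll, s0,
            args=(free, fixed, y, X, Km, blocks, env),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-7},
        )
        if -res.fun > best_ll:
            best_theta, best_ll = res.x, -res.fun
            converged = bool(res.success)

    if sub is not None and sub.loglik >= best_ll - 1e-8:
        # boundary attains the maximum: adopt the λg = 0 solution exactly
        best_ll = sub.loglik
        best_theta = np.array(
            [getattr(sub.params, p) for p in free]
        )
        converged = converged or sub.converged

    full_vec = np.array(
        [fixed.get(p, np.nan) for p in _PARAM_NAMES], dtype=float
    )
    for name, v in zip(free, best_theta):
        full_vec[_PARAM_NAMES.index(name)] = v
    _, beta, _ = _block_loglik(best_theta, free, fixed, y, X, Km, blocks, env)
    params = GxEParameters.from_vector(full_vec, beta=beta)

    ses = {name: np.nan for name in free}
    if compute_ses:
        ses = _numeric_ses(best_theta, free, fixed, y, X, Km, blocks, env, bounds)

    fit = GxEFit(
        params=params,
        ses=ses,
        loglik=float(best_ll),
        constraints=constraints,
        converged=converged,
        n=n,
    )
    if cache is not None:
        cache[constraints] = fit
    return fit
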