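"""Likelihood-ratio tests with mixture-χ² nulls and the two-stage protocol.

Variance parameters constrained to a boundary of the parameter space under
the null do not yield the textbook χ² reference for the likelihood-ratio
statistic Λ = −2(lnL_null − lnL_alt); the asymptotic null is a mixture of
χ² distributions (possibly including a point mass at zero).  The specific
references used here:

* stage 1, interaction model vs. polygenic (γg, γe free; λg ≥ 0 on its
  boundary): 50:50 mixture of χ²(2) and χ²(3);
* γg = 0 or γe = 0 (interior parameters): χ²(1);
* λg = 0 (boundary): 50:50 mixture of a point mass at 0 and χ²(1).

The two-stage protocol first asks whether the full interaction model beats
the polygenic model at all, then tests each interaction parameter singly.
A parameter whose SE exceeds its |MLE| *and* whose single-parameter test is
non-significant is judged unimportant and dropped; the remaining tests are
then rerun against the reduced alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .gxe import TESTABLE_PARAMS, EnvironmentIndex, GxEFit, fit_gxe
from .polygenic import PolygenicFit, fit_polygenic

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureChiSquare",
    "LRTResult",
    "TwoStageReport",
    "STAGE1_REFERENCE",
    "VARIANCE_REFERENCE",
    "BOUNDARY_REFERENCE",
    "reference_for",
    "mixture_sf",
    "lrt",
    "stage1_test",
    "stage2_tests",
    "select_model",
    "run_two_stage",
    "format_pvalue",
]


@dataclass(frozen=True)
class MixtureChiSquare:
    """Finite mixture of χ² distributions; df = 0 is a point mass at zero."""

    components: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        weights = [w for w, _ in self.components]
        dfs = [df for _, df in self.components]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-12:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if any(df < 0 or df != int(df) for df in dfs):
            raise ValueError("degrees of freedom must be non-negative integers")
        if sum(df == 0 for df in dfs) > 1:
            raise ValueError("at most one point-mass component")

    def sf(self, x: float) -> float:
        """Upper-tail probability P(X >= x)."""
        if x < 0:
            raise ValueError("LRT statistic must be non-negative")
        out = 0.0
        for w, df in self.components:
            if df == 0:
                out += w * (1.0 if x <= 0 else 0.0)
            else:
                out += w * float(chi2.sf(x, df))
        return out

    def describe(self) -> str:
        return " + ".join(
            f"{w:g}*{'pointmass0' if df == 0 else f'chi2({df})'}"
            for w, df in self.components
        )


#: stage-1 reference: interaction model adds γg, γe and boundary λg
STAGE1_REFERENCE = MixtureChiSquare(((0.5, 2), (0.5, 3)))
#: single interior parameter (γg or γe) constrained to 0
VARIANCE_REFERENCE = MixtureChiSquare(((1.0, 1),))
#: single boundary parameter (λg) constrained to 0
BOUNDARY_REFERENCE = MixtureChiSquare(((0.5, 0), (0.5, 1)))


def reference_for(param: str) -> MixtureChiSquare:
    """Single-parameter reference distribution for a stage-2 test."""
    if param == "lambda_g":
        return BOUNDARY_REFERENCE
    if param in ("gamma_g", "gamma_e"):
        return VARIANCE_REFERENCE
    raise ValueError(f"no test defined for parameter {param!r}")


def mixture_sf(x: float, ref: MixtureChiSquare) -> float:
    """Upper tail of a mixture-χ² reference at x."""
    return ref.sf(x)


@dataclass
class LRTResult:
    """A likelihood-ratio test outcome against a mixture-χ² reference."""

    statistic: float
    reference: MixtureChiSquare
    p_value: float
    null_loglik: float
    alt_loglik: float
    label: str = ""

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "reference": self.reference.describe(),
            "null_loglik": float(self.null_loglik),
            "alt_loglik": float(self.alt_loglik),
        }


def lrt(
    null_loglik: float,
    alt_loglik: float,
    ref: MixtureChiSquare,
    label: str = "",
) -> LRTResult:
    """Λ = −2(lnL_null − lnL_alt) with its mixture-χ² p-value.

    Small negative Λ (within 1e−6) from independent numerical
    optimizations is clamped to 0; anything more negative indicates the
    alternative fit failed to dominate its nested null and triggers a
    refit warning.
    """
    stat = -2.0 * (null_loglik - alt_loglik)
    if stat < -1e-6:
        logger.warning(
            "negative LRT statistic %.3g (%s): alternative fit likely "
            "not converged; refit recommended", stat, label or "unlabeled"
        )
    stat = max(stat, 0.0)
    return LRTResult(
        statistic=stat,
        reference=ref,
        p_value=ref.sf(stat),
        null_loglik=null_loglik,
        alt_loglik=alt_loglik,
        label=label,
    )


def stage1_test(polygenic: PolygenicFit, full_gxe: GxEFit) -> LRTResult:
    """Overall interaction test: full GxE model vs. polygenic null."""
    if polygenic.n != full_gxe.n:
        raise ValueError("polygenic and GxE fits use different samples")
    if full_gxe.constraints:
        raise ValueError("stage-1 alternative must be the unconstrained fit")
    return lrt(polygenic.loglik, full_gxe.loglik, STAGE1_REFERENCE, label="stage1")


def stage2_tests(
    alternative: GxEFit, null_fits: dict[str, GxEFit]
) -> list[LRTResult]:
    """Single-parameter tests of each free interaction parameter.

    Each null fit must constrain exactly the tested parameter beyond the
    alternative's constraints; references are χ²(1) for γg and γe and the
    50:50 point-mass/χ²(1) mixture for boundary λg.
    """
    results = []
    for param, null_fit in null_fits.items():
        if param in alternative.constraints:
            raise ValueError(f"{param} is constrained in the alternative model")
        expected = alternative.constraints | {param}
        if null_fit.constraints != expected:
            raise ValueError(
                f"null fit for {param} constrains {sorted(null_fit.constraints)}, "
                f"expected {sorted(expected)}"
            )
        results.append(
            lrt(null_fit.loglik, alternative.loglik, reference_for(param),
                label=param)
        )
    return results


def select_model(
    full: GxEFit,
    formal_tests: dict[str, LRTResult],
    alpha: float = 0.05,
) -> frozenset:
    """Decide which interaction parameters to drop into a reduced model.

    A parameter is dropped only when both conditions hold: its SE exceeds
    its |MLE| (an MLE above twice its SE being the usual likelihood-theory
    marker of significance; an unavailable SE counts as exceeding), and
    its formal single-parameter test is non-significant at ``alpha``.
    """
    drop = set()
    for param in TESTABLE_PARAMS:
        if param in full.constraints or param not in formal_tests:
            continue
        se = full.se(param)
        mle = abs(full.param(param))
        se_dominates = np.isnan(se) or se > mle
        if se_dominates and not formal_tests[param].significant(alpha):
            drop.add(param)
    return frozenset(drop)


@dataclass
class TwoStageReport:
    """Full record of the two-stage protocol for one trait×environment dyad."""

    polygenic: PolygenicFit
    full_fit: GxEFit
    stage1: LRTResult
    formal_tests: dict[str, LRTResult]
    dropped: frozenset
    model_used: str  # "full" | "reduced"
    alternative: GxEFit
    stage2: list[LRTResult] = field(default_factory=list)
    trait: str = ""
    environment: str = ""

    def stage2_for(self, param: str) -> LRTResult | None:
        for r in self.stage2:
            if r.label == param:
                return r
        return None

    def to_record(self) -> dict:
        return {
            "trait": self.trait,
            "environment": self.environment,
            "n": int(self.polygenic.n),
            "polygenic": self.polygenic.to_record(),
            "full_gxe": self.full_fit.to_record(),
            "stage1": self.stage1.to_record(),
            "formal_tests": {k: v.to_record() for k, v in self.formal_tests.items()},
            "dropped": sorted(self.dropped),
            "model_used": self.model_used,
            "alternative": self.alternative.to_record(),
            "stage2": [r.to_record() for r in self.stage2],
        }


def run_two_stage(
    y,
    X=None,
    K=None,
    env: EnvironmentIndex | None = None,
    alpha: float = 0.05,
    trait: str = "",
    environment: str = "",
    compute_ses: bool = True,
) -> TwoStageReport:
    """Fit and test one trait×environment dyad end to end.

    Fits the polygenic and full interaction models, performs the stage-1
    overall test, screens the three interaction parameters (SE vs. MLE
    plus formal single-parameter tests), optionally reduces the model, and
    reruns the remaining stage-2 tests against the selected alternative.
    Nested fits are shared through a constraint-keyed cache.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    cache: dict = {}
    poly = fit_polygenic(y, X, K)
    full = fit_gxe(y, X, K, env, constraints=(), poly=poly, cache=cache,
                   compute_ses=compute_ses)
    s1 = stage1_test(poly, full)

    formal_nulls = {
        p: fit_gxe(y, X, K, env, constraints={p}, poly=poly, cache=cache,
                   compute_ses=False)
        for p in TESTABLE_PARAMS
    }
    formal = {r.label: r for r in stage2_tests(full, formal_nulls)}

    dropped = select_model(full, formal, alpha=alpha) if compute_ses else frozenset()
    if dropped:
        alt = fit_gxe(y, X, K, env, constraints=dropped, poly=poly, cache=cache,
                      compute_ses=False)
        model_used = "reduced"
        remaining = [p for p in TESTABLE_PARAMS if p not in dropped]
        nulls = {
            p: fit_gxe(y, X, K, env, constraints=dropped | {p}, poly=poly,
                       cache=cache, compute_ses=False)
            for p in remaining
        }
        stage2 = stage2_tests(alt, nulls)
    else:
        alt = full
        model_used = "full"
        stage2 = [formal[p] for p in TESTABLE_PARAMS if p in formal]

    return TwoStageReport(
        polygenic=poly,
        full_fit=full,
        stage1=s1,
        formal_tests=formal,
        dropped=dropped,
        model_used=model_used,
        alternative=alt,
        stage2=stage2,
        trait=trait,
        environment=environment,
    )


def format_pvalue(p: float) -> str:
    """Four significant figures; scientific notation below 1e−3."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p != 0.0 and p < 1e-3:
        return f"{p:.1E}"
    return f"{p:.4g}"
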