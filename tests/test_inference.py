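"""Mixture-χ² references, LRT arithmetic and the two-stage protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from famgxe.gxe import EnvironmentIndex, GxEParameters
from famgxe.inference import (
    BOUNDARY_REFERENCE,
    STAGE1_REFERENCE,
    VARIANCE_REFERENCE,
    MixtureChiSquare,
    format_pvalue,
    lrt,
    mixture_sf,
    run_two_stage,
    select_model,
    stage1_test,
    stage2_tests,
)
from famgxe.pedigree import compute_kinship
from famgxe.simulate import (
    SimulationConfig,
    generate_pedigree,
    simulate_environment,
    simulate_phenotype,
)


class TestMixtureSf:
    def test_at_zero_is_one(self):
        for ref in (STAGE1_REFERENCE, VARIANCE_REFERENCE, BOUNDARY_REFERENCE):
            assert mixture_sf(0.0, ref) == 1.0

    def test_boundary_mixture_published_value(self):
        # genetic-correlation test of the cardiovascular risk score dyad
        assert mixture_sf(3.2609, BOUNDARY_REFERENCE) == pytest.approx(
            0.0355, abs=5e-5
        )

    def test_chi2_1_published_value(self):
        # residual-variance heterogeneity test of the same dyad
        assert mixture_sf(6.8624, VARIANCE_REFERENCE) == pytest.approx(
            0.0088, abs=5e-5
        )

    def test_stage1_mixture_published_value(self):
        assert mixture_sf(10.303, STAGE1_REFERENCE) == pytest.approx(0.01, abs=5e-3)

    def test_single_component_equals_chi2(self):
        ref = MixtureChiSquare(((1.0, 4),))
        for x in (0.5, 2.0, 9.7):
            assert mixture_sf(x, ref) == pytest.approx(chi2.sf(x, 4), abs=1e-14)

    def test_point_mass_contributes_only_at_zero(self):
        ref = MixtureChiSquare(((0.5, 0), (0.5, 1)))
        assert mixture_sf(0.0, ref) == 1.0
        assert mixture_sf(1e-12, ref) == pytest.approx(0.5 * chi2.sf(1e-12, 1))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(0, 60), st.floats(0, 60))
    def test_non_increasing(self, a, b):
        lo, hi = sorted((a, b))
        for ref in (STAGE1_REFERENCE, BOUNDARY_REFERENCE):
            assert mixture_sf(lo, ref) >= mixture_sf(hi, ref)

    @pytest.mark.parametrize(
        "components",
        [((0.6, 1), (0.6, 2)), ((0.5, 0), (0.25, 0), (0.25, 1)), ()],
    )
    def test_invalid_mixture_rejected(self, components):
        with pytest.raises(ValueError):
            MixtureChiSquare(tuple(components))


class TestLrt:
    def test_published_stage1_statistic(self):
        res = lrt(-547.8467, -542.6951, STAGE1_REFERENCE)
        assert res.statistic == pytest.approx(10.303, abs=1.5e-3)
        assert res.p_value == pytest.approx(0.01, abs=5e-3)

    def test_published_variance_statistic(self):
        res = lrt(-538.4800, -534.6063, VARIANCE_REFERENCE)
        assert res.statistic == pytest.approx(7.7474, abs=1.5e-3)
        assert res.p_value == pytest.approx(0.0054, abs=5e-5)

    def test_published_gamma_e_statistic(self):
        res = lrt(-546.3321, -542.9009, VARIANCE_REFERENCE)
        assert res.statistic == pytest.approx(6.8624, abs=1.5e-3)

    def test_equal_logliks(self):
        res = lrt(-10.0, -10.0, STAGE1_REFERENCE)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_small_negative_clamped(self, caplog):
        res = lrt(-10.0, -10.0 - 1e-8, STAGE1_REFERENCE)
        assert res.statistic == 0.0

    def test_large_negative_warns(self, caplog):
        with caplog.at_level("WARNING"):
            lrt(-10.0, -11.0, STAGE1_REFERENCE)
        assert "refit" in caplog.text

    def test_additivity_over_nested_triple(self):
        a, b, c = -547.8467, -544.5313, -542.6951
        lam_ab = lrt(a, b, VARIANCE_REFERENCE).statistic
        lam_bc = lrt(b, c, VARIANCE_REFERENCE).statistic
        lam_ac = lrt(a, c, VARIANCE_REFERENCE).statistic
        assert lam_ab + lam_bc == pytest.approx(lam_ac, abs=1e-6)


class _FakeFit:
    """Minimal stand-in mimicking a fitted interaction model (synthetic)."""

    def __init__(self, params, ses, loglik=0.0, constraints=frozenset(), n=100):
        self._params = params
        self._ses = ses
        self.loglik = loglik
        self.constraints = frozenset(constraints)
        self.n = n

    def param(self, name):
        return self._params.get(name, 0.0)

    def se(self, name):
        return self._ses.get(name, np.nan)


class _FakeTest:
    def __init__(self, p):
        self.p_value = p

    def significant(self, alpha=0.05):
        return self.p_value < alpha


class TestSelectModel:
    def test_drops_weak_nonsignificant(self):
        full = _FakeFit({"gamma_g": 0.01, "lambda_g": 0.2, "gamma_e": -0.3},
                        {"gamma_g": 0.05, "lambda_g": 0.05, "gamma_e": 0.05})
        tests = {"gamma_g": _FakeTest(0.96), "lambda_g": _FakeTest(0.01),
                 "gamma_e": _FakeTest(0.01)}
        assert select_model(full, tests) == frozenset({"gamma_g"})

    def test_all_strong_keeps_full_model(self):
        full = _FakeFit({"gamma_g": 0.3, "lambda_g": 0.2, "gamma_e": -0.3},
                        {"gamma_g": 0.05, "lambda_g": 0.05, "gamma_e": 0.05})
        tests = {k: _FakeTest(0.001) for k in ("gamma_g", "lambda_g", "gamma_e")}
        assert select_model(full, tests) == frozenset()

    def test_weak_but_significant_retained(self):
        full = _FakeFit({"gamma_g": 0.01}, {"gamma_g": 0.05})
        tests = {"gamma_g": _FakeTest(0.01)}
        assert select_model(full, tests) == frozenset()

    def test_nan_se_counts_as_weak(self):
        full = _FakeFit({"lambda_g": 0.0}, {"lambda_g": np.nan})
        tests = {"lambda_g": _FakeTest(0.5)}
        assert select_model(full, tests) == frozenset({"lambda_g"})


class TestStage2Bookkeeping:
    def test_mismatched_constraints_rejected(self):
        alt = _FakeFit({}, {}, constraints=frozenset())
        null = _FakeFit({}, {}, constraints=frozenset({"gamma_g", "gamma_e"}))
        with pytest.raises(ValueError, match="null fit"):
            stage2_tests(alt, {"gamma_g": null})

    def test_param_constrained_in_alternative_rejected(self):
        alt = _FakeFit({}, {}, constraints=frozenset({"gamma_g"}))
        null = _FakeFit({}, {}, constraints=frozenset({"gamma_g"}))
        with pytest.raises(ValueError, match="constrained"):
            stage2_tests(alt, {"gamma_g": null})

    def test_mismatched_samples_rejected(self):
        poly = _FakeFit({}, {}, n=100)
        full = _FakeFit({}, {}, n=90)
        with pytest.raises(ValueError, match="different samples"):
            stage1_test(poly, full)


def _dataset(seed, n_families, truth):
    cfg = SimulationConfig(n_families=n_families, seed=seed, true_params=truth)
    ped = generate_pedigree(cfg)
    k = compute_kinship(ped)
    q = simulate_environment(ped, k, 0.41, 10.16, 3.92, seed + 1)
    table = simulate_phenotype(ped, k, q, truth, cfg, seed + 2)
    return k, q, table["trait"].to_numpy()


class TestRunTwoStage:
    def test_report_structure(self):
        truth = GxEParameters(alpha_g=np.log(0.4), alpha_e=np.log(0.6))
        k, q, y = _dataset(3, 10, truth)
        rep = run_two_stage(y, None, k, EnvironmentIndex(q))
        assert rep.stage1 is not None
        assert 1 <= len(rep.stage2) <= 3
        labels = {t.label for t in rep.stage2}
        assert labels <= {"gamma_g", "lambda_g", "gamma_e"}
        if rep.model_used == "reduced":
            assert rep.dropped and rep.alternative.constraints == rep.dropped
        rec = rep.to_record()
        assert set(rec) >= {"stage1", "stage2", "polygenic", "full_gxe"}

    def test_power_against_strong_interaction(self):
        truth = GxEParameters(alpha_g=np.log(0.5), gamma_g=0.4, lambda_g=0.1,
                              alpha_e=np.log(0.5))
        hits = 0
        for seed in range(5):
            k, q, y = _dataset(60 + seed, 14, truth)
            rep = run_two_stage(y, None, k, EnvironmentIndex(q),
                                compute_ses=False)
            hits += rep.stage1.significant(0.05)
        assert hits >= 4

    def test_null_mostly_non_significant(self):
        truth = GxEParameters(alpha_g=np.log(0.4), alpha_e=np.log(0.6))
        hits = 0
        for seed in range(8):
            k, q, y = _dataset(200 + seed, 8, truth)
            rep = run_two_stage(y, None, k, EnvironmentIndex(q),
                                compute_ses=False)
            hits += rep.stage1.significant(0.05)
        assert hits <= 2


class TestFormatPvalue:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0355, "0.0355"), (0.5, "0.5"), (7.9e-5, "7.9E-05"),
         (9.78e-7, "9.8E-07"), (1.0, "1"), (0.0, "0")],
    )
    def test_formats(self, p, expected):
        assert format_pvalue(p) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            format_pvalue(1.5)
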