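"""Interaction covariance model: functions, assembly, likelihood, fitting."""

import numpy as np
import pytest

from conftest import random_pedigree
from famgxe.gxe import (
    EnvironmentIndex,
    GxEParameters,
    assemble_covariance,
    fit_gxe,
    genetic_correlation_between,
    genetic_variance_at,
    gxe_loglik,
    residual_variance_at,
    two_environment_gxe_variance,
)
from famgxe.pedigree import compute_kinship
from famgxe.polygenic import fit_polygenic, polygenic_loglik
from famgxe.simulate import (
    SimulationConfig,
    generate_pedigree,
    simulate_environment,
    simulate_phenotype,
)
from oracles import dense_mvn_loglik


class TestVarianceCorrelationFunctions:
    @pytest.mark.parametrize(
        "alpha, gamma, dq, expected",
        [(0.0, 0.0, 3.0, 1.0), (np.log(2), 0.0, 0.0, 2.0),
         (0.0, 0.5, 2.0, np.e)],
    )
    def test_genetic_variance(self, alpha, gamma, dq, expected):
        assert genetic_variance_at(alpha, gamma, dq, 0.0) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "lam, qi, qj, expected",
        [(0.3, 4.0, 4.0, 1.0), (0.0, -2.0, 9.0, 1.0),
         (0.1, 0.0, 10.0, np.exp(-1))],
    )
    def test_genetic_correlation(self, lam, qi, qj, expected):
        assert genetic_correlation_between(lam, qi, qj) == pytest.approx(expected)
        assert genetic_correlation_between(lam, qj, qi) == pytest.approx(expected)

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError):
            genetic_correlation_between(-0.1, 0.0, 1.0)

    def test_residual_variance_monotone(self):
        q = np.linspace(0, 10, 11)
        v = residual_variance_at(0.0, -0.2, q, 5.0)
        assert np.all(np.diff(v) < 0)
        assert residual_variance_at(0.0, -0.2, 10.0, 5.0) == pytest.approx(
            np.exp(-1.0)
        )

    @pytest.mark.parametrize(
        "s1, s2, rho, expected",
        [(1.0, 1.0, 1.0, 0.0), (1.0, 1.0, 0.5, 1.0), (1.0, 4.0, 1.0, 1.0),
         (2.0, 2.0, 0.0, 4.0)],
    )
    def test_two_environment_variance(self, s1, s2, rho, expected):
        assert two_environment_gxe_variance(s1, s2, rho) == pytest.approx(expected)


class TestAssembleCovariance:
    def test_reduces_to_polygenic(self, rng):
        ped = random_pedigree(rng)
        k = compute_kinship(ped).values
        q = rng.uniform(0, 12, k.shape[0])
        params = GxEParameters(alpha_g=np.log(0.4), alpha_e=np.log(0.6))
        sigma = assemble_covariance(k, params, EnvironmentIndex(q))
        np.testing.assert_array_equal(
            sigma, k * 0.4 + np.eye(k.shape[0]) * 0.6
        )

    def test_unrelated_pair_zero_covariance(self):
        k = np.eye(2)
        params = GxEParameters(gamma_g=0.5, lambda_g=0.2)
        sigma = assemble_covariance(k, params, EnvironmentIndex([1.0, 9.0]))
        assert sigma[0, 1] == 0.0

    def test_half_sib_decay_value(self):
        k = np.array([[1.0, 0.5], [0.5, 1.0]])
        env = EnvironmentIndex([0.0, 10.0], q_bar=5.0)
        params = GxEParameters(alpha_g=0.0, gamma_g=0.0, lambda_g=0.1,
                               alpha_e=-50.0)
        sigma = assemble_covariance(k, params, env)
        assert sigma[0, 1] == pytest.approx(0.5 * np.exp(-1.0), abs=1e-9)

    def test_diagonal_formula(self, rng):
        ped = random_pedigree(rng)
        k = compute_kinship(ped).values
        n = k.shape[0]
        q = rng.uniform(0, 12, n)
        env = EnvironmentIndex(q)
        params = GxEParameters(alpha_g=0.1, gamma_g=0.25, lambda_g=0.05,
                               alpha_e=-0.3, gamma_e=-0.1)
        sigma = assemble_covariance(k, params, env)
        expected = (
            genetic_variance_at(0.1, 0.25, q, env.q_bar) * k.diagonal()
            + residual_variance_at(-0.3, -0.1, q, env.q_bar)
        )
        np.testing.assert_allclose(sigma.diagonal(), expected, atol=1e-12)
        np.testing.assert_allclose(sigma, sigma.T)

    def test_shift_invariance(self, rng):
        ped = random_pedigree(rng)
        k = compute_kinship(ped).values
        q = rng.uniform(0, 12, k.shape[0])
        params = GxEParameters(gamma_g=0.3, lambda_g=0.1, gamma_e=-0.2)
        s1 = assemble_covariance(k, params, EnvironmentIndex(q))
        s2 = assemble_covariance(k, params, EnvironmentIndex(q + 100.0))
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_monotone_variance_heterogeneity(self):
        k = np.eye(5)
        q = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        params = GxEParameters(gamma_g=0.4, alpha_e=-50.0)
        sigma = assemble_covariance(k, params, EnvironmentIndex(q))
        assert np.all(np.diff(sigma.diagonal()) > 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_definite_for_valid_params(self, seed):
        rg = np.random.default_rng(seed)
        ped = random_pedigree(rg)
        k = compute_kinship(ped).values
        q = rg.uniform(0, 12, k.shape[0])
        params = GxEParameters(
            alpha_g=rg.uniform(-1, 1), gamma_g=rg.uniform(-0.4, 0.4),
            lambda_g=rg.uniform(0, 0.3), alpha_e=rg.uniform(-1, 1),
            gamma_e=rg.uniform(-0.4, 0.4),
        )
        sigma = assemble_covariance(k, params, EnvironmentIndex(q))
        np.linalg.cholesky(sigma)  # raises if not PD


class TestGxELoglik:
    def test_reduces_to_polygenic_loglik(self, rng):
        ped = random_pedigree(rng)
        k = compute_kinship(ped).values
        n = k.shape[0]
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        q = rng.uniform(0, 12, n)
        params = GxEParameters(alpha_g=np.log(0.4), alpha_e=np.log(0.6),
                               beta=np.array([0.2]))
        ll = gxe_loglik(params, y, X, k, EnvironmentIndex(q))
        ll_poly = polygenic_loglik(0.4, 0.6, [0.2], y, X, k)
        assert ll == pytest.approx(ll_poly, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_mvn_oracle(self, seed):
        rg = np.random.default_rng(100 + seed)
        ped = random_pedigree(rg, max_members=15)
        k = compute_kinship(ped).values
        n = k.shape[0]
        y = rg.standard_normal(n)
        X = np.column_stack([np.ones(n), rg.standard_normal(n)])
        beta = rg.standard_normal(2)
        q = rg.uniform(0, 12, n)
        env = EnvironmentIndex(q)
        params = GxEParameters(
            alpha_g=rg.uniform(-1, 1), gamma_g=rg.uniform(-0.3, 0.3),
            lambda_g=rg.uniform(0, 0.2), alpha_e=rg.uniform(-1, 1),
            gamma_e=rg.uniform(-0.3, 0.3), beta=beta,
        )
        ll = gxe_loglik(params, y, X, k, env)
        oracle = dense_mvn_loglik(
            y, X @ beta, assemble_covariance(k, params, env)
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_permutation_invariance(self, rng):
        ped = random_pedigree(rng, max_members=15)
        k = compute_kinship(ped).values
        n = k.shape[0]
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        q = rng.uniform(0, 12, n)
        params = GxEParameters(gamma_g=0.2, lambda_g=0.1, beta=np.array([0.0]))
        perm = rng.permutation(n)
        ll = gxe_loglik(params, y, X, k, EnvironmentIndex(q))
        ll_p = gxe_loglik(
            params, y[perm], X[perm], k[np.ix_(perm, perm)],
            EnvironmentIndex(q[perm], q_bar=float(q.mean())),
        )
        assert ll == pytest.approx(ll_p, abs=1e-10)


def _small_dataset(seed, n_families=12, params=None):
    cfg = SimulationConfig(n_families=n_families, seed=seed,
                           true_params=params or GxEParameters())
    ped = generate_pedigree(cfg)
    k = compute_kinship(ped)
    q = simulate_environment(ped, k, 0.41, 10.16, 3.92, seed + 1)
    table = simulate_phenotype(ped, k, q, cfg.true_params, cfg, seed + 2)
    return k, q, table


class TestFitGxE:
    def test_fully_constrained_recovers_polygenic(self):
        k, q, table = _small_dataset(1)
        y = table["trait"].to_numpy()
        poly = fit_polygenic(y, None, k)
        fit = fit_gxe(y, None, k, EnvironmentIndex(q),
                      constraints={"gamma_g", "lambda_g", "gamma_e"}, poly=poly)
        assert fit.loglik == pytest.approx(poly.loglik, abs=1e-6)
        assert fit.param("gamma_g") == 0.0
        assert fit.param("lambda_g") == 0.0
        assert fit.param("gamma_e") == 0.0

    def test_nesting_monotone(self):
        k, q, table = _small_dataset(2)
        y = table["trait"].to_numpy()
        env = EnvironmentIndex(q)
        cache = {}
        poly = fit_polygenic(y, None, k)
        full = fit_gxe(y, None, k, env, poly=poly, cache=cache)
        lls = {c: f.loglik for c, f in cache.items()}
        for c1, ll1 in lls.items():
            for c2, ll2 in lls.items():
                if c1 < c2:  # c1 less constrained
                    assert ll1 >= ll2 - 1e-6
        assert full.loglik >= poly.loglik - 1e-6

    def test_invalid_constraint_rejected(self):
        with pytest.raises(ValueError, match="constrain"):
            fit_gxe(np.zeros(30), None, np.eye(30),
                    EnvironmentIndex(np.arange(30.0)), constraints={"alpha_g"})

    def test_recovery_moderate_sample(self):
        truth = GxEParameters(alpha_g=0.0, gamma_g=0.3, lambda_g=0.05,
                              alpha_e=0.0, gamma_e=-0.2)
        k, q, table = _small_dataset(5, n_families=30, params=truth)
        y = table["trait"].to_numpy()
        from famgxe.preprocess import covariate_design

        X = covariate_design(
            table["age"].to_numpy(), (table["sex"] == "male").to_numpy(float)
        )
        fit = fit_gxe(y, X, k, EnvironmentIndex(q))
        assert fit.converged
        for p in ("gamma_g", "gamma_e"):
            se = fit.se(p)
            assert np.isfinite(se) and se > 0
            assert abs(fit.param(p) - getattr(truth, p)) < 4 * se
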