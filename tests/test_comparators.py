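"""Tests for the LMM/PQL-based comparison resampling methods."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from brass.comparators import (
    binarize_replicates,
    fit_lmm_null,
    logmm_sample_replicates,
    mvnpermute_replicates,
    naive_replicates,
    pql_fit,
)
from brass.model_core import kinship_eigen
from brass.transform import ReplicateSet
from tests.conftest import sib_block_phi


@pytest.fixture(scope="module")
def lmm_data():
    rng = np.random.default_rng(14)
    phi = sib_block_phi(25)           # n = 100
    n = phi.shape[0]
    x = np.column_stack([np.ones(n), rng.standard_normal(n)])
    chol = np.linalg.cholesky(0.6 * phi + 0.4 * np.eye(n))
    y = x @ np.array([0.3, -0.5]) + chol @ rng.standard_normal(n)
    return y, x, phi


class TestLmmFit:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(15)
        n = 120
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ np.array([1.0, 2.0]) + rng.standard_normal(n)
        fit = fit_lmm_null(y, x, np.eye(n))
        beta_ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.max(np.abs(fit.beta_hat - beta_ols)) < 1e-6
        assert fit.sigma1_sq == pytest.approx(0.0, abs=1e-8)

    def test_gls_normal_equations(self, lmm_data):
        y, x, phi = lmm_data
        fit = fit_lmm_null(y, x, phi)
        v = fit.sigma1_sq * phi + fit.sigma2_sq * np.eye(len(y))
        score = x.T @ np.linalg.solve(v, fit.residuals)
        assert np.max(np.abs(score)) < 1e-6

    def test_variance_component_recovery(self):
        """REML recovers (sigma1^2, sigma2^2) on average over simulated data."""
        rng = np.random.default_rng(16)
        phi = sib_block_phi(100)      # n = 400
        n = phi.shape[0]
        eig = kinship_eigen(phi, validate=False)
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        s1, s2 = 0.7, 0.5
        chol = np.linalg.cholesky(s1 * phi + s2 * np.eye(n))
        est = []
        for _ in range(60):
            y = x @ np.array([0.2, 0.4]) + chol @ rng.standard_normal(n)
            fit = fit_lmm_null(y, x, eig=eig)
            est.append([fit.sigma1_sq, fit.sigma2_sq])
        est = np.array(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert abs(est[:, 0].mean() - s1) < 4 * se[0] + 0.02
        assert abs(est[:, 1].mean() - s2) < 4 * se[1] + 0.02


class TestPermutationComparators:
    def test_identity_permutation_recovers_trait(self, lmm_data, identity_rng):
        y, x, phi = lmm_data
        fit = fit_lmm_null(y, x, phi)
        naive = naive_replicates(fit, 2, rng=identity_rng)
        assert np.max(np.abs(naive.replicates - y[None, :])) < 1e-8
        mvn = mvnpermute_replicates(fit, x, n_reps=2, rng=identity_rng)
        assert np.max(np.abs(mvn.replicates - y[None, :])) < 1e-8

    def test_naive_preserves_mean_and_variance(self):
        rng = np.random.default_rng(17)
        n = 40
        x = np.ones((n, 1))           # intercept-only: fitted mean is constant
        y = rng.standard_normal(n) + 1.0
        fit = fit_lmm_null(y, x, np.eye(n))
        reps = naive_replicates(fit, 20, seed=2)
        assert np.allclose(reps.replicates.mean(axis=1), y.mean())
        assert np.allclose(reps.replicates.var(axis=1), y.var())

    def test_naive_matches_exhaustive_enumeration(self):
        """n = 4: every sampled replicate appears in the 24-permutation oracle."""
        y = np.array([0.0, 1.0, 1.0, 0.0])
        x = np.ones((4, 1))
        fit = fit_lmm_null(y, x, np.eye(4))
        resid = fit.residuals
        mean = (x @ fit.beta_hat)
        oracle = {tuple(np.round(mean + np.array(p), 12))
                  for p in itertools.permutations(resid)}
        reps = naive_replicates(fit, 200, seed=3)
        for row in reps.replicates:
            assert tuple(np.round(row, 12)) in oracle

    def test_mvnpermute_matches_enumeration_under_identity_phi(self):
        """Phi = I, intercept-only: permuting centered residuals orthonormally.

        The second-moment matrix over sampled replicates matches the average
        over all 24 enumerated permutations of the whitened residuals.
        """
        rng = np.random.default_rng(18)
        y = np.array([0.2, 1.4, -0.6, 0.9])
        x = np.ones((4, 1))
        fit = fit_lmm_null(y, x, np.eye(4))
        reps = mvnpermute_replicates(fit, x, n_reps=4000, seed=4).replicates
        # enumeration oracle in the replicate space
        d = np.sqrt(fit.sigma1_sq + fit.sigma2_sq)
        w = x / d
        q, _ = np.linalg.qr(w, mode="complete")
        v = q[:, 1:]
        zeta = v.T @ (fit.residuals / d)
        mean_fit = x @ fit.beta_hat
        oracle_rows = [mean_fit + d * (v @ np.array(p))
                       for p in itertools.permutations(zeta)]
        oracle_second = np.mean([np.outer(r, r) for r in oracle_rows], axis=0)
        emp_second = reps.T @ reps / reps.shape[0]
        assert np.max(np.abs(emp_second - oracle_second)) < 0.1

    def test_replicates_are_permutations_in_whitened_space(self, lmm_data):
        y, x, phi = lmm_data
        fit = fit_lmm_null(y, x, phi)
        reps = mvnpermute_replicates(fit, x, n_reps=10, seed=5)
        assert reps.replicates.shape == (10, len(y))
        # every replicate preserves the GLS mean-model fit exactly:
        v = fit.sigma1_sq * phi + fit.sigma2_sq * np.eye(len(y))
        vi = np.linalg.inv(v)
        for row in reps.replicates:
            score = x.T @ (vi @ (row - x @ fit.beta_hat))
            assert np.max(np.abs(score)) < 1e-6


class TestPql:
    def test_no_structure_limit_matches_logistic(self):
        """Data generated with sigma^2 = 0: PQL collapses to logistic regression."""
        import statsmodels.api as sm_api

        rng = np.random.default_rng(19)
        phi = sib_block_phi(75)       # n = 300
        n = phi.shape[0]
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(0.3 + 0.8 * x[:, 1])).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = pql_fit(y, x, phi)
        oracle = sm_api.Logit(y, x).fit(disp=0)
        assert np.max(np.abs(fit.beta_hat - oracle.params)) < 1e-3
        assert np.all((fit.m_hat > 0) & (fit.m_hat < 1))

    def test_variance_component_biased_downward(self):
        """PQL underestimates sigma^2 for binary traits (documented bias)."""
        rng = np.random.default_rng(20)
        phi = sib_block_phi(75, rho=0.9)   # strong blocks, n = 300
        n = phi.shape[0]
        eig = kinship_eigen(phi, validate=False)
        chol = np.linalg.cholesky(phi + 1e-8 * np.eye(n))
        x = np.ones((n, 1))
        sigma2_true = 1.5
        est = []
        for _ in range(25):
            u = np.sqrt(sigma2_true) * (chol @ rng.standard_normal(n))
            y = (rng.random(n) < expit(-0.5 + u)).astype(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est.append(pql_fit(y, x, eig=eig).sigma_sq)
        est = np.array(est)
        assert est.mean() > 0.0
        assert est.mean() < sigma2_true      # downward bias direction


class TestLogmmSampling:
    def test_replicates_are_binary_bernoulli_half(self):
        rng = np.random.default_rng(22)
        n = 50
        x = np.ones((n, 1))
        y = (rng.random(n) < 0.5).astype(float)
        eig = kinship_eigen(np.eye(n), validate=False)
        from brass.comparators import LogmmFit
        fit = LogmmFit(y=y, x=x, eig=eig, beta_hat=np.zeros(1), sigma_sq=0.0,
                       u_hat=np.zeros(n), m_hat=np.full(n, 0.5),
                       working_converged=True)
        reps = logmm_sample_replicates(fit, x, n_reps=2000, seed=6)
        assert reps.binary
        assert set(np.unique(reps.replicates)) <= {0.0, 1.0}
        assert abs(reps.replicates.mean() - 0.5) < 4 * 0.5 / np.sqrt(2000 * n)

    def test_within_block_correlation_matches_quadrature(self):
        """Perfectly-correlated blocks: trait correlation matches the
        logit-normal moments computed by Gauss-Hermite quadrature."""
        sigma2 = 2.0
        n = 4
        phi = np.kron(np.eye(2), np.ones((2, 2)))   # two blocks of size 2
        eig = kinship_eigen(phi, validate=False)
        x = np.ones((n, 1))
        from brass.comparators import LogmmFit
        fit = LogmmFit(y=np.array([0, 1, 0, 1.0]), x=x, eig=eig,
                       beta_hat=np.zeros(1), sigma_sq=sigma2,
                       u_hat=np.zeros(n), m_hat=np.full(n, 0.5),
                       working_converged=True)
        reps = logmm_sample_replicates(fit, x, n_reps=40000, seed=7).replicates
        # quadrature oracle: u ~ N(0, sigma2) shared within block
        z, wts = np.polynomial.hermite_e.hermegauss(80)
        u = z * np.sqrt(sigma2)
        p1 = np.sum(wts * expit(u)) / wts.sum()
        p11 = np.sum(wts * expit(u) ** 2) / wts.sum()
        corr_oracle = (p11 - p1**2) / (p1 * (1 - p1))
        pair = reps[:, :2]
        corr_emp = np.corrcoef(pair[:, 0], pair[:, 1])[0, 1]
        assert abs(corr_emp - corr_oracle) < 0.02
        assert abs(pair.mean() - p1) < 0.01


class TestBinarize:
    def test_case_count_preserved_and_fixed_point(self):
        rng = np.random.default_rng(23)
        y = np.array([1.0, 0, 0, 1, 0, 1, 0, 0, 0, 0])
        raw = rng.standard_normal((30, 10))
        raw[0] = y                   # a replicate already equal to Y
        reps = ReplicateSet(replicates=raw, seed=None, binary=False, method="brass")
        out = binarize_replicates(reps, y)
        assert out.binary
        assert np.all(out.replicates.sum(axis=1) == 3)
        assert np.array_equal(out.replicates[0], y)

    def test_negated_trait_flips_to_controls(self):
        """Replicate = -Y puts former controls on top; verified by a sort oracle."""
        y = np.array([1.0, 0, 0, 1, 0, 1, 0, 0, 0, 0])
        reps = ReplicateSet(replicates=-y[None, :], seed=None, binary=False,
                            method="naive")
        out = binarize_replicates(reps, y).replicates[0]
        order = np.argsort(-(-y), kind="stable")     # brute-force stable sort
        expected = np.zeros(10)
        expected[order[:3]] = 1.0
        assert np.array_equal(out, expected)
        assert np.all(out[y == 1] == 0)              # every former case is now 0

    @given(st.integers(1, 9), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_case_count_always_exact(self, n_cases, seed):
        rng = np.random.default_rng(seed)
        y = np.zeros(10)
        y[:n_cases] = 1.0
        raw = rng.standard_normal((5, 10))
        out = binarize_replicates(
            ReplicateSet(replicates=raw, seed=None, binary=False, method="m"), y)
        assert np.all(out.replicates.sum(axis=1) == n_cases)

    def test_rejects_binary_input(self):
        y = np.array([1.0, 0, 1])
        reps = ReplicateSet(replicates=y[None, :], seed=None, binary=True,
                            method="logmm-pql")
        with pytest.raises(ValueError):
            binarize_replicates(reps, y)
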