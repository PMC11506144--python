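"""REML correctness: oracles, gradient checks, invariances, BLUP behavior."""

import numpy as np
import pytest

import mtgblup as mg
from mtgblup.reml import EigenGRM, pack_bivariate, reml_single, restricted_loglik


def _dense_reml_loglik(sa, se, y, g):
    """Independent dense REML log-likelihood (mean absorbed), for oracles."""
    n = y.shape[0]
    v = sa * g + se * np.eye(n)
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0:
        return -np.inf
    vi = np.linalg.inv(v)
    one = np.ones(n)
    cxx = one @ vi @ one
    p = vi - np.outer(vi @ one, one @ vi) / cxx
    return -0.5 * (logdet + np.log(cxx) + y @ p @ y)


def _dense_reml_loglik_bi(m_cov, r_cov, y2, g):
    """Dense bivariate REML log-likelihood via explicit Kronecker matrices."""
    n = y2.shape[0]
    v = np.kron(m_cov, g) + np.kron(r_cov, np.eye(n))
    sign, logdet = np.linalg.slogdet(v)
    if sign <= 0:
        return -np.inf
    vi = np.linalg.inv(v)
    x = np.kron(np.eye(2), np.ones((n, 1)))
    c = x.T @ vi @ x
    signc, logdetc = np.linalg.slogdet(c)
    if signc <= 0:
        return -np.inf
    yv = y2.T.ravel()
    p = vi - vi @ x @ np.linalg.solve(c, x.T @ vi)
    return -0.5 * (logdet + logdetc + yv @ p @ yv)


@pytest.fixture(scope="module")
def toy_data6(toy_grm6):
    rng = np.random.default_rng(7)
    L = np.linalg.cholesky(toy_grm6)
    y = 2.0 + L @ rng.normal(size=6) + rng.normal(scale=0.8, size=6)
    return y, toy_grm6


class TestRestrictedLoglik:
    def test_matches_dense_formula_single(self, toy_data6):
        y, g = toy_data6
        for sa, se in [(0.5, 1.0), (2.0, 0.3), (1.1, 1.1)]:
            ll, _ = restricted_loglik(np.array([sa, se]), y, g)
            assert ll == pytest.approx(_dense_reml_loglik(sa, se, y, g), abs=1e-8)

    def test_matches_dense_formula_bivariate(self, toy_grm6):
        rng = np.random.default_rng(8)
        y2 = rng.normal(size=(6, 2))
        m_cov = np.array([[1.5, 0.4], [0.4, 0.9]])
        r_cov = np.array([[1.0, -0.2], [-0.2, 2.0]])
        ll, _ = restricted_loglik(pack_bivariate(m_cov, r_cov), y2, toy_grm6)
        assert ll == pytest.approx(_dense_reml_loglik_bi(m_cov, r_cov, y2, toy_grm6), abs=1e-8)

    def test_gradient_matches_finite_differences(self, toy_grm6):
        rng = np.random.default_rng(9)
        n = 8
        w = rng.normal(size=(n, 16))
        g = w @ w.T / 16 + 0.05 * np.eye(n)
        y1 = rng.normal(size=n)
        theta1 = np.array([0.7, 1.3])
        _, grad = restricted_loglik(theta1, y1, g)
        for k in range(2):
            e = np.zeros(2)
            e[k] = 1e-6
            lp, _ = restricted_loglik(theta1 + e, y1, g)
            lm, _ = restricted_loglik(theta1 - e, y1, g)
            assert grad[k] == pytest.approx((lp - lm) / 2e-6, rel=1e-4)
        y2 = rng.normal(size=(n, 2))
        theta2 = np.array([1.2, 0.3, 0.9, 1.5, -0.2, 2.0])
        _, grad2 = restricted_loglik(theta2, y2, g)
        for k in range(6):
            e = np.zeros(6)
            e[k] = 1e-6
            lp, _ = restricted_loglik(theta2 + e, y2, g)
            lm, _ = restricted_loglik(theta2 - e, y2, g)
            assert grad2[k] == pytest.approx((lp - lm) / 2e-6, rel=1e-4)

    def test_translation_invariance(self, toy_data6):
        y, g = toy_data6
        theta = np.array([1.0, 0.7])
        ll_a, _ = restricted_loglik(theta, y, g)
        ll_b, _ = restricted_loglik(theta, y + 123.4, g)
        assert ll_a == pytest.approx(ll_b, abs=1e-8)

    def test_bivariate_nests_two_singles(self, toy_grm6):
        # with zero genetic and residual covariance the bivariate REML
        # log-likelihood decouples into the sum of the single-trait ones
        rng = np.random.default_rng(10)
        y2 = rng.normal(size=(6, 2))
        m_cov = np.diag([1.3, 0.8])
        r_cov = np.diag([0.9, 1.7])
        ll_bi, _ = restricted_loglik(pack_bivariate(m_cov, r_cov), y2, toy_grm6)
        ll_1, _ = restricted_loglik(np.array([1.3, 0.9]), y2[:, 0], toy_grm6)
        ll_2, _ = restricted_loglik(np.array([0.8, 1.7]), y2[:, 1], toy_grm6)
        assert ll_bi == pytest.approx(ll_1 + ll_2, abs=1e-8)

    def test_non_pd_parameters_rejected(self, toy_data6):
        y, g = toy_data6
        with pytest.raises(ValueError, match="positive-definite"):
            restricted_loglik(np.array([-5.0, 0.1]), y, g)


class TestSingleTraitFit:
    def test_grid_search_oracle(self, toy_data6):
        y, g = toy_data6
        grid = np.linspace(0.01, 6.0, 200)
        best, arg = -np.inf, None
        for sa in grid:
            for se in grid:
                ll = _dense_reml_loglik(sa, se, y, g)
                if ll > best:
                    best, arg = ll, (sa, se)
        eig = EigenGRM.from_matrix(g)
        theta, log, _ = reml_single(y, eig)
        spacing = grid[1] - grid[0]
        assert log.converged
        assert abs(theta[0] - arg[0]) <= spacing
        assert abs(theta[1] - arg[1]) <= spacing
        # and the REML optimum is at least as good as the best grid point
        ll_hat, _ = restricted_loglik(theta, y, g)
        assert ll_hat >= best - 1e-8

    def test_loglik_monotone_over_accepted_steps(self, founders_small):
        grm = mg.compute_grm(founders_small.dosages())
        rng = np.random.default_rng(11)
        y = rng.normal(size=grm.n)
        res = mg.fit_single(y, list(grm.ids), grm)
        lls = [r["loglik"] for r in res.convergence.records]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_scale_equivariance(self, grm_small):
        rng = np.random.default_rng(12)
        L = np.linalg.cholesky(grm_small.values)
        y = L @ rng.normal(size=grm_small.n) + rng.normal(size=grm_small.n)
        a = mg.fit_single(y, list(grm_small.ids), grm_small)
        b = mg.fit_single(10.0 * y, list(grm_small.ids), grm_small)
        assert b.varcomp.sigma_a2 == pytest.approx(100 * a.varcomp.sigma_a2, rel=1e-3)
        assert b.varcomp.sigma_e2 == pytest.approx(100 * a.varcomp.sigma_e2, rel=1e-3)
        assert np.allclose(b.gebv(), 10.0 * a.gebv(), rtol=1e-3, atol=1e-8)

    def test_constant_phenotype_degenerates_gracefully(self, grm_small):
        res = mg.fit_single(np.full(grm_small.n, 3.14), list(grm_small.ids), grm_small)
        assert res.convergence.status == "degenerate"
        assert np.all(res.gebv() == 0)

    def test_non_pd_grm_rejected(self):
        g = np.zeros((4, 4))
        with pytest.raises(np.linalg.LinAlgError):
            EigenGRM.from_matrix(g)

    def test_candidate_gebv_matches_projection(self, founders_small):
        # candidates enter through G's covariance structure: for them the
        # zero-incidence MME solution equals sigma_a^2 G_co V^{-1}(y - mu)
        grm = mg.compute_grm(founders_small.dosages())
        obs = list(grm.ids[:250])
        rng = np.random.default_rng(13)
        L = np.linalg.cholesky(grm.values)
        gtrue = L @ rng.normal(size=grm.n)
        y = gtrue[:250] + rng.normal(size=250)
        res = mg.fit_single(y, obs, grm)
        sa, se = res.varcomp.sigma_a2, res.varcomp.sigma_e2
        v = sa * grm.values[:250, :250] + se * np.eye(250)
        py = np.linalg.solve(v, y - res.blup.mu[0])
        manual = sa * grm.values[250:, :250] @ py
        assert np.allclose(res.gebv(list(grm.ids[250:])), manual, rtol=1e-6, atol=1e-8)


class TestBivariateFit:
    def test_random_search_oracle_n5(self):
        rng = np.random.default_rng(14)
        w = rng.normal(size=(5, 10))
        g = w @ w.T / 10 + 0.05 * np.eye(5)
        y2 = rng.normal(size=(5, 2))
        eig = EigenGRM.from_matrix(g)
        from mtgblup.reml import reml_bivariate

        theta, log, _ = reml_bivariate(y2, eig)
        ll_hat, _ = restricted_loglik(theta, y2, g)
        best = -np.inf
        for _ in range(1000):
            a = rng.normal(size=(2, 2)) * 0.8
            b = rng.normal(size=(2, 2)) * 0.8
            cand = pack_bivariate(a @ a.T + 0.01 * np.eye(2), b @ b.T + 0.01 * np.eye(2))
            ll, _ = restricted_loglik(cand, y2, g)
            best = max(best, ll)
        assert ll_hat >= best - 1e-6

    def test_decoupled_traits_reduce_to_single(self, founders_small):
        # traits simulated with no genetic or residual cross-covariance:
        # bivariate GEBVs collapse onto the single-trait GEBVs
        grm = mg.compute_grm(founders_small.dosages())
        rng = np.random.default_rng(15)
        L = np.linalg.cholesky(grm.values)
        n = grm.n
        y1 = L @ rng.normal(size=n) + 0.8 * rng.normal(size=n)
        y2 = L @ rng.normal(size=n) + 0.8 * rng.normal(size=n)
        ids = list(grm.ids)
        bi = mg.fit_multi(y1, y2, ids, grm)
        s1 = mg.fit_single(y1, ids, grm)
        s2 = mg.fit_single(y2, ids, grm)
        assert abs(bi.genetic_correlation) < 0.35
        assert np.corrcoef(bi.gebv(0), s1.gebv())[0, 1] > 0.99
        assert np.corrcoef(bi.gebv(1), s2.gebv())[0, 1] > 0.99

    def test_loglik_monotone_over_accepted_steps(self, grm_small):
        rng = np.random.default_rng(16)
        y2 = rng.normal(size=(grm_small.n, 2))
        res = mg.fit_multi(y2[:, 0], y2[:, 1], list(grm_small.ids), grm_small)
        lls = [r["loglik"] for r in res.convergence.records]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_estimated_m_and_r_positive_definite(self, grm_small):
        rng = np.random.default_rng(17)
        L = np.linalg.cholesky(grm_small.values)
        gg = L @ rng.normal(size=(grm_small.n, 2))
        y2 = gg + rng.normal(size=(grm_small.n, 2))
        res = mg.fit_multi(y2[:, 0], y2[:, 1], list(grm_small.ids), grm_small)
        assert np.linalg.eigvalsh(res.varcomp.m_cov).min() > 0
        assert np.linalg.eigvalsh(res.varcomp.r_cov).min() > 0

    def test_mismatched_phenotype_sets_rejected(self, grm_small):
        y = np.zeros(grm_small.n)
        y2 = y.copy()
        y2[0] = np.nan
        with pytest.raises(ValueError, match="design"):
            mg.BivariateGBLUP(y, y2, list(grm_small.ids), grm_small)


def test_summary_tables_render(grm_small):
    rng = np.random.default_rng(18)
    L = np.linalg.cholesky(grm_small.values)
    y = L @ rng.normal(size=grm_small.n) + rng.normal(size=grm_small.n)
    s = mg.fit_single(y, list(grm_small.ids), grm_small).summary()
    assert "sigma_a^2" in s and "h^2" in s
    y2 = L @ rng.normal(size=grm_small.n) + rng.normal(size=grm_small.n)
    b = mg.fit_multi(y, y2, list(grm_small.ids), grm_small).summary()
    assert "genetic correlation" in b
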