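import numpy as np
import pytest
from scipy import stats

from famrv.lmm import fit_null, single_marker_test
from famrv.settests import (
    ChiSquareMixture,
    UndefinedTestError,
    burden_score,
    fam_burden_test,
    fam_skat_quadratic,
    fam_skat_test,
    mixture_pvalue,
)

from conftest import sib_pair_phi
from test_lmm import simulate_sib_pairs


def ols_skat_oracle(y, x, g_cols, weights):
    """Plain (unrelated-sample) SKAT computed from first principles.

    OLS residuals, explicit n x n kernel, dense eigendecomposition, and a
    Gil-Pelaez inversion on a fixed grid — sharing no code path with the
    package implementation.
    """
    n, p = x.shape
    h = x @ np.linalg.solve(x.T @ x, x.T)
    r = y - h @ y
    sigma2 = (r @ r) / (n - p)
    gw = g_cols * np.asarray(weights)[None, :]
    # package convention: Q built with Sigma^-1 = I/sigma2
    q_obs = float(r @ gw @ gw.T @ r) / sigma2**2
    m = (np.eye(n) - h) / sigma2
    lam = np.linalg.eigvalsh(gw.T @ m @ gw)
    lam = lam[lam > 1e-10 * lam.max()]
    # Gil-Pelaez / Imhof on a trapezoid grid (independent of package code)
    # lower limit ~0: the integrand tends to (sum(lam) - q)/2 there, so the
    # omitted [0, 1e-10] sliver contributes < 1e-7 to p
    u = np.linspace(1e-10, 400.0 / lam.max(), 2_000_001)
    theta = 0.5 * (np.arctan(np.multiply.outer(u, lam)).sum(1) - q_obs * u)
    rho = np.exp(0.25 * np.log1p(np.square(np.multiply.outer(u, lam))).sum(1))
    integrand = np.sin(theta) / (u * rho)
    p_val = 0.5 + np.trapezoid(integrand, u) / np.pi
    return q_obs, lam, p_val


class TestBurden:
    def test_burden_score_is_weighted_sum(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.1, (50, 6)).astype(float)
        w = rng.uniform(1, 25, 6)
        out = burden_score(g, w)
        oracle = np.array([sum(w[j] * g[i, j] for j in range(6)) for i in range(50)])
        np.testing.assert_allclose(out, oracle)
        # duplicated column behaves additively
        gg = np.column_stack([g[:, 0], g[:, 0]])
        np.testing.assert_allclose(
            burden_score(gg, np.array([2.0, 3.0])), 5.0 * g[:, 0]
        )

    def test_single_variant_burden_equals_single_marker_test(self):
        rng = np.random.default_rng(1)
        y, x, phi = simulate_sib_pairs(80, 1.0, 1.0, rng)
        g = rng.binomial(2, 0.15, len(y)).astype(float)
        fit = fit_null(y, x, phi)
        b = fam_burden_test(fit, burden_score(g[:, None], np.array([1.0])))
        s = single_marker_test(fit, g)
        assert b.p == pytest.approx(s.p, rel=1e-12)
        assert b.stat == pytest.approx(s.stat, rel=1e-12)

    def test_unrelated_case_equals_ols_f_score(self):
        """With Phi = I and sigma_g2 = 0 the famBT score test matches the OLS
        score test of the burden covariate."""
        rng = np.random.default_rng(2)
        n = 250
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, 0.05, (n, 5)).astype(float)
        w = np.full(5, 2.0)
        y = x @ [0.5, -0.2] + rng.standard_normal(n)
        fit = fit_null(y, x, np.eye(n))
        res = fam_burden_test(fit, burden_score(g, w))
        gb = burden_score(g, w)
        h = x @ np.linalg.solve(x.T @ x, x.T)
        r, gx = y - h @ y, gb - h @ gb
        sigma2 = (r @ r) / (n - 2)
        stat = (gx @ r) ** 2 / (sigma2 * (gx @ gx))
        assert res.stat == pytest.approx(stat, rel=1e-6)
        assert res.p == pytest.approx(float(stats.chi2.sf(stat, 1)), rel=1e-6)

    def test_wald_and_score_agree_in_well_behaved_case(self):
        rng = np.random.default_rng(3)
        y, x, phi = simulate_sib_pairs(150, 1.0, 1.0, rng)
        g = rng.binomial(2, 0.2, (len(y), 4)).astype(float)
        gb = burden_score(g, np.ones(4))
        fit = fit_null(y, x, phi)
        score = fam_burden_test(fit, gb)
        wald = fam_burden_test(fit, gb, method="wald", y=y, x=x, phi=phi)
        assert wald.p == pytest.approx(score.p, rel=0.05)

    def test_constant_burden_is_undefined(self):
        rng = np.random.default_rng(4)
        y, x, phi = simulate_sib_pairs(20, 1.0, 1.0, rng)
        fit = fit_null(y, x, phi)
        with pytest.raises(UndefinedTestError):
            fam_burden_test(fit, np.zeros(len(y)))


class TestMixturePvalue:
    def test_single_eigenvalue_is_chi_square(self):
        p, how = mixture_pvalue(ChiSquareMixture(np.array([1.0]), 3.841458820694124))
        assert p == pytest.approx(0.05, abs=1e-7)
        assert how == "exact-chi2"

    def test_equal_eigenvalues_scaled_chi_square(self):
        p, _ = mixture_pvalue(
            ChiSquareMixture(np.array([2.0, 2.0]), 2 * 5.991464547107979)
        )
        assert p == pytest.approx(0.05, rel=1e-6)

    @pytest.mark.parametrize(
        "lam, q",
        [
            ([3.0, 1.0, 0.5], 10.0),
            ([5.0, 5.0, 1.0, 0.2], 25.0),
            ([10.0, 1.0], 4.0),
            ([1.0, 1.0, 1.0, 1.0, 1.0], 11.0),
            ([50.0, 20.0, 5.0, 1.0, 0.1, 0.01], 120.0),
        ],
    )
    def test_matches_monte_carlo_tail(self, lam, q):
        """Imhof inversion agrees with 1e6-draw Monte-Carlo tails within 3 SE."""
        lam = np.array(lam)
        p, _ = mixture_pvalue(ChiSquareMixture(lam, q))
        rng = np.random.default_rng(int(q * 101))
        draws = (lam[None, :] * rng.chisquare(1, (10**6, lam.size))).sum(1)
        p_mc = (draws > q).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / 1e6)
        assert abs(p - p_mc) < 3 * se

    def test_no_positive_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            ChiSquareMixture(np.array([]), 1.0)

    def test_never_returns_zero(self):
        p, _ = mixture_pvalue(ChiSquareMixture(np.array([1.0, 0.5]), 1e6))
        assert p > 0


class TestFamSkat:
    def test_q1_set_equals_weighted_single_variant_test(self):
        """A one-variant famSKAT p equals the single-marker score p (the
        one-eigenvalue mixture is a scaled chi-square, and weights cancel)."""
        rng = np.random.default_rng(5)
        y, x, phi = simulate_sib_pairs(90, 1.0, 1.0, rng)
        g = rng.binomial(2, 0.1, len(y)).astype(float)
        fit = fit_null(y, x, phi)
        skat = fam_skat_test(fit, g[:, None], np.array([7.7]))
        single = single_marker_test(fit, g)
        assert skat.p == pytest.approx(single.p, rel=1e-9)

    def test_unrelated_case_matches_plain_skat_oracle(self):
        """With Phi = I, sigma_g2 = 0, famSKAT reproduces an independently
        coded plain-SKAT computation (Q, eigenvalues and p) to 1e-6."""
        rng = np.random.default_rng(6)
        n = 150
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, 0.08, (n, 4)).astype(float)
        w = np.array([3.0, 9.0, 1.0, 5.0])
        y = x @ [1.0, 0.3] + rng.standard_normal(n)
        fit = fit_null(y, x, np.eye(n))
        mix = fam_skat_quadratic(fit, g, w)
        q_o, lam_o, p_o = ols_skat_oracle(y, x, g, w)
        assert mix.q_obs == pytest.approx(q_o, rel=1e-8)
        np.testing.assert_allclose(np.sort(mix.eigenvalues), np.sort(lam_o),
                                   rtol=1e-8)
        p, _ = mixture_pvalue(mix)
        assert p == pytest.approx(p_o, abs=1e-6)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(7)
        y, x, phi = simulate_sib_pairs(100, 1.0, 1.0, rng)
        g = rng.binomial(2, 0.1, (len(y), 3)).astype(float)
        w = np.array([1.0, 4.0, 2.0])
        fit = fit_null(y, x, phi)
        p1 = fam_skat_test(fit, g, w).p
        p2 = fam_skat_test(fit, g, 13.7 * w).p
        assert p2 == pytest.approx(p1, rel=1e-9)
        b1 = fam_burden_test(fit, burden_score(g, w)).p
        b2 = fam_burden_test(fit, burden_score(g, 13.7 * w)).p
        assert b2 == pytest.approx(b1, rel=1e-9)

    def test_reordering_invariance(self):
        rng = np.random.default_rng(8)
        y, x, phi = simulate_sib_pairs(70, 1.0, 1.0, rng)
        g = rng.binomial(2, 0.12, (len(y), 3)).astype(float)
        w = np.array([2.0, 1.0, 3.0])
        perm = rng.permutation(len(y))
        p1 = fam_skat_test(fit_null(y, x, phi), g, w).p
        p2 = fam_skat_test(
            fit_null(y[perm], x[perm], phi[np.ix_(perm, perm)]), g[perm], w
        ).p
        b1 = fam_burden_test(fit_null(y, x, phi), burden_score(g, w)).p
        b2 = fam_burden_test(
            fit_null(y[perm], x[perm], phi[np.ix_(perm, perm)]),
            burden_score(g[perm], w),
        ).p
        assert p2 == pytest.approx(p1, rel=1e-6)
        assert b2 == pytest.approx(b1, rel=1e-6)

    def test_small_case_matches_sampling_oracle(self):
        """famSKAT p on n = 12, q = 3 agrees with Monte-Carlo sampling of the
        fitted chi-square mixture within 3 MC SE."""
        rng = np.random.default_rng(9)
        phi = sib_pair_phi(6)
        n = 12
        x = np.ones((n, 1))
        g = rng.binomial(2, 0.3, (n, 3)).astype(float)
        y = rng.standard_normal(n)
        fit = fit_null(y, x, phi)
        mix = fam_skat_quadratic(fit, g, np.ones(3))
        p, _ = mixture_pvalue(mix)
        draws = (mix.eigenvalues[None, :]
                 * rng.chisquare(1, (10**6, mix.eigenvalues.size))).sum(1)
        p_mc = (draws > mix.q_obs).mean()
        se = max(np.sqrt(p_mc * (1 - p_mc) / 1e6), 1e-6)
        assert abs(p - p_mc) < 3 * se

    def test_rank_zero_kernel_rejected(self):
        rng = np.random.default_rng(10)
        y, x, phi = simulate_sib_pairs(20, 1.0, 1.0, rng)
        fit = fit_null(y, x, phi)
        with pytest.raises(UndefinedTestError):
            fam_skat_quadratic(fit, np.zeros((len(y), 2)), np.ones(2))

    def test_ignoring_kinship_inflates_null_rejections(self):
        """Forcing Phi = I on related null data yields more small p-values
        than the kinship-adjusted analysis (demonstration, not a rate claim)."""
        rng = np.random.default_rng(11)
        rej_adj = rej_naive = 0
        for _ in range(40):
            y, x, phi = simulate_sib_pairs(100, 2.0, 0.5, rng)
            g = (rng.random((len(y), 5)) < 0.05).astype(float)
            w = np.ones(5)
            fit_adj = fit_null(y, x, phi)
            fit_naive = fit_null(y, x, np.eye(len(y)))
            rej_adj += fam_skat_test(fit_adj, g, w).p < 0.2
            rej_naive += fam_skat_test(fit_naive, g, w).p < 0.2
        assert rej_naive >= rej_adj
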