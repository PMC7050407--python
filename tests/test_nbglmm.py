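"""Unit and property tests for the NB GLM/GLMM engine."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from asekit import nbglmm as nb
from asekit.nbglmm import (
    NbGlmmData,
    NbGlmmFit,
    bh_fdr,
    fit_nb_glm,
    fit_nb_glmm,
    loglik_oracle,
    wald_test,
)

from conftest import brute_force_bh, make_2x2_data

LN2 = np.log(2.0)


def oracle_fixture_dataset(rng, n_subj=None):
    """Deep, weakly-overdispersed paired counts for quadrature cross-checks.

    At ~1000 reads per observation and near-Poisson dispersion the Laplace
    approximation error is far below the comparison tolerance, so any
    disagreement with the quadrature oracle reflects an implementation
    defect rather than approximation error.
    """
    if n_subj is None:
        n_subj = int(rng.integers(4, 7))
    subj = np.repeat(np.arange(n_subj), 2)
    grp = np.repeat((np.arange(n_subj) % 2).astype(float), 2)
    allele = np.tile([0.0, 1.0], n_subj)
    b = rng.normal(0, 0.25, n_subj)
    mu = np.exp(np.log(1000.0) + 0.2 * allele + 0.4 * allele * grp + b[subj])
    y = rng.poisson(mu)
    X = np.column_stack([np.ones(2 * n_subj), allele, grp, allele * grp])
    return NbGlmmData(
        y=y,
        X=X,
        names=("intercept", "allele", "group", "allele:group"),
        subject=subj,
    )


def random_glmm_dataset(rng, n_subj=None, depth=100.0):
    """A small random paired-count dataset with known design."""
    if n_subj is None:
        n_subj = int(rng.integers(4, 7))
    subj = np.repeat(np.arange(n_subj), 2)
    # alternate groups so the design always has full rank
    grp = np.repeat((np.arange(n_subj) % 2).astype(float), 2)
    allele = np.tile([0.0, 1.0], n_subj)
    b = rng.normal(0, 0.3, n_subj)
    mu = np.exp(np.log(depth / 2) + 0.2 * allele + 0.4 * allele * grp + b[subj])
    y = rng.negative_binomial(8, 8 / (8 + mu))
    X = np.column_stack([np.ones(2 * n_subj), allele, grp, allele * grp])
    return NbGlmmData(
        y=y,
        X=X,
        names=("intercept", "allele", "group", "allele:group"),
        subject=subj,
    )


class TestNbGlm:
    def test_saturated_fit_recovers_closed_form_interaction(self):
        # one observation per cell forces fitted means = observed counts
        data = make_2x2_data((100, 50, 100, 100))
        fit = fit_nb_glm(data)
        assert fit.status == "converged"
        assert fit.coef("allele:group") == pytest.approx(LN2, abs=1e-6)
        assert fit.coef("allele") == pytest.approx(np.log(0.5), abs=1e-6)

    def test_equal_cells_give_zero_effects(self):
        fit = fit_nb_glm(make_2x2_data((80, 80, 80, 80)))
        for name in ("allele", "group", "allele:group"):
            assert fit.coef(name) == pytest.approx(0.0, abs=1e-6)

    def test_label_swap_flips_interaction_sign(self):
        data = make_2x2_data((100, 50, 100, 100), reps=3)
        swapped = make_2x2_data((50, 100, 100, 100), reps=3)
        f1, f2 = fit_nb_glm(data), fit_nb_glm(swapped)
        assert f1.coef("allele") == pytest.approx(-f2.coef("allele"), abs=1e-6)
        assert f1.coef("allele:group") == pytest.approx(
            -f2.coef("allele:group"), abs=1e-6
        )

    def test_theta_recovery_matches_independent_nb_regression(self, rng):
        # ML dispersion on simulated data, cross-checked against statsmodels
        n = 200
        x = rng.random(n)
        mu = np.exp(2.0 + 0.8 * x)
        theta_true = 5.0
        y = rng.negative_binomial(theta_true, theta_true / (theta_true + mu))
        X = np.column_stack([np.ones(n), x])
        data = NbGlmmData(y=y, X=X, names=("intercept", "x"))
        fit = fit_nb_glm(data, dispersion="ml")
        assert fit.theta == pytest.approx(theta_true, rel=0.3)

        import statsmodels.api as sm

        sm_fit = sm.NegativeBinomial(y, X).fit(disp=0)
        # statsmodels alpha = 1/theta
        assert fit.theta == pytest.approx(1.0 / sm_fit.params[-1], rel=0.05)
        assert fit.beta[1] == pytest.approx(sm_fit.params[1], abs=1e-3)

    def test_all_zero_cell_is_flagged_degenerate(self):
        fit = fit_nb_glm(make_2x2_data((100, 0, 100, 50), reps=2))
        assert fit.status == "degenerate"
        assert np.all(np.abs(fit.beta) <= nb.COEF_CAP)


class TestNbGlmm:
    def test_sigma_fixed_at_zero_reduces_to_glm(self, rng):
        data = random_glmm_dataset(rng)
        glm = fit_nb_glm(data)
        glmm0 = fit_nb_glmm(data, fix_sigma_b=0.0)
        np.testing.assert_allclose(glmm0.beta, glm.beta, atol=1e-6)
        assert glmm0.sigma_b == 0.0

    def test_label_swap_symmetry_within_tolerance(self, rng):
        data = random_glmm_dataset(rng, n_subj=10, depth=80)
        X2 = data.X.copy()
        X2[:, 1] = 1 - X2[:, 1]
        X2[:, 3] = X2[:, 1] * X2[:, 2]
        data2 = NbGlmmData(y=data.y, X=X2, names=data.names, subject=data.subject)
        f1, f2 = fit_nb_glmm(data), fit_nb_glmm(data2)
        assert f1.coef("allele") == pytest.approx(-f2.coef("allele"), abs=1e-6)
        assert f1.coef("allele:group") == pytest.approx(
            -f2.coef("allele:group"), abs=1e-6
        )

    def test_analytic_gradient_matches_numeric(self, rng):
        data = random_glmm_dataset(rng, n_subj=8)
        g = nb._GroupedData(data)
        p = np.array([3.0, 0.1, 0.2, 0.3, np.log(8.0), np.log(0.25)])
        k = 4

        def fun(p):
            beta, a, c = p[:k], p[k], p[k + 1]
            th, s2 = np.exp(a), np.exp(2 * c)
            b, D, mu = nb._laplace_parts(g, beta, th, s2, np.zeros(g.n_subj))
            return nb._laplace_loglik(g, beta, th, s2, b, D, mu), nb._laplace_grad(
                g, beta, th, s2, b, D, mu
            )

        _, grad = fun(p)
        num = np.zeros_like(p)
        for j in range(p.size):
            pp, pm = p.copy(), p.copy()
            pp[j] += 1e-6
            pm[j] -= 1e-6
            num[j] = (fun(pp)[0] - fun(pm)[0]) / 2e-6
        np.testing.assert_allclose(grad, num, atol=1e-5)

    def test_laplace_close_to_quadrature_on_small_fits(self, rng):
        # deep, weakly-overdispersed counts: the regime where the Laplace
        # approximation is sharp, so a discrepancy indicates a defect
        checked = 0
        while checked < 5:
            data = oracle_fixture_dataset(rng)
            fit = fit_nb_glmm(data, dispersion="ml")
            if not fit.ok or fit.sigma_b == 0.0:
                continue
            ll_gh = loglik_oracle(fit.beta, fit.theta, fit.sigma_b, data, 32)
            assert abs(fit.loglik - ll_gh) < 1e-3
            checked += 1


class TestOracle:
    def test_wald_p_from_laplace_and_quadrature_curvature_agree(self, rng):
        # information from the Laplace objective vs from the GH loglik
        from scipy.stats import norm as normal

        def hessian(fun, p):
            k = p.size
            H = np.zeros((k, k))
            h = 1e-4 * np.maximum(1.0, np.abs(p))
            f0 = fun(p)
            for i in range(k):
                for j in range(i, k):
                    pp = p.copy(); pp[i] += h[i]; pp[j] += h[j]
                    pi = p.copy(); pi[i] += h[i]
                    pj = p.copy(); pj[j] += h[j]
                    H[i, j] = H[j, i] = (
                        fun(pp) - fun(pi) - fun(pj) + f0
                    ) / (h[i] * h[j])
            return 0.5 * (H + H.T)

        checked = 0
        while checked < 3:
            data = oracle_fixture_dataset(rng)
            fit = fit_nb_glmm(data, dispersion="ml")
            if not fit.ok or fit.sigma_b == 0.0:
                continue
            g = nb._GroupedData(data)
            k = 4
            p0 = np.concatenate(
                [fit.beta, [np.log(fit.theta), np.log(fit.sigma_b)]]
            )

            def neg_laplace(p):
                beta, th, s2 = p[:k], np.exp(p[k]), np.exp(2 * p[k + 1])
                b, D, mu = nb._laplace_parts(g, beta, th, s2, np.zeros(g.n_subj))
                return -nb._laplace_loglik(g, beta, th, s2, b, D, mu)

            def neg_gh(p):
                return -loglik_oracle(
                    p[:k], float(np.exp(p[k])), float(np.exp(p[k + 1])), data, 32
                )

            ps = []
            for fun in (neg_laplace, neg_gh):
                V = np.linalg.inv(hessian(fun, p0))
                z = p0[3] / np.sqrt(V[3, 3])
                ps.append(2 * normal.sf(abs(z)))
            assert ps[0] == pytest.approx(ps[1], rel=0.10)
            checked += 1

    def test_zero_sigma_equals_fixed_effect_loglik(self, rng):
        data = random_glmm_dataset(rng)
        beta = np.array([3.0, 0.1, 0.0, 0.2])
        ll = loglik_oracle(beta, 10.0, 0.0, data)
        eta = data.X @ beta
        expected = float(np.sum(nb.nb_logpmf(data.y, np.exp(eta), 10.0)))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_node_doubling_converged(self, rng):
        data = random_glmm_dataset(rng)
        beta = np.array([3.0, 0.1, 0.0, 0.2])
        l32 = loglik_oracle(beta, 10.0, 0.3, data, 32)
        l64 = loglik_oracle(beta, 10.0, 0.3, data, 64)
        assert abs(l32 - l64) < 1e-8

    def test_truth_beats_perturbed_parameters_on_average(self, rng):
        beta_true = np.array([3.0, 0.2, 0.0, 0.5])
        diffs = []
        for _ in range(20):
            data = random_glmm_dataset(rng, n_subj=6, depth=40)
            lt = loglik_oracle(beta_true, 8.0, 0.3, data)
            lp = loglik_oracle(beta_true + np.array([1, 0, 0, 0]), 8.0, 0.3, data)
            diffs.append(lt - lp)
        assert np.mean(diffs) > 0

    def test_too_few_nodes_rejected(self, rng):
        data = random_glmm_dataset(rng)
        with pytest.raises(ValueError):
            loglik_oracle(np.zeros(4), 10.0, 0.3, data, n_nodes=4)


class TestWald:
    def _fit(self, est, se):
        vcov = np.array([[se**2]])
        return NbGlmmFit(
            beta=np.array([est]),
            names=("b",),
            theta=10.0,
            sigma_b=0.0,
            vcov=vcov,
            loglik=0.0,
            status="converged",
            n_obs=10,
            n_subjects=5,
        )

    def test_zero_estimate_gives_p_one(self):
        assert wald_test(self._fit(0.0, 1.0), "b").p_value == pytest.approx(1.0)

    def test_critical_z_gives_p_005(self):
        w = wald_test(self._fit(1.959964, 1.0), "b")
        assert w.p_value == pytest.approx(0.05, abs=1e-6)

    def test_p_matches_numeric_normal_integration(self):
        w = wald_test(self._fit(1.3, 0.7), "b")
        tail, _ = integrate.quad(norm.pdf, abs(w.z), np.inf)
        assert w.p_value == pytest.approx(2 * tail, rel=1e-8)

    def test_degenerate_fit_rejected(self):
        f = self._fit(1.0, 1.0)
        f.status = "degenerate"
        with pytest.raises(ValueError):
            wald_test(f, "b")


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.005, 0.9], [0.01, 0.9]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = np.round(rng.random(m), 3)  # rounding produces ties
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_dominates_p_and_bh_rejects_superset_of_bonferroni(self, rng):
        p = rng.random(100)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        alpha = 0.05
        bonf = p < alpha / len(p)
        bh = q < alpha
        assert np.all(bh[bonf])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])


class TestDataValidation:
    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            NbGlmmData(y=[1, 2, 3, 4], X=X, names=("a", "b"))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            NbGlmmData(y=[1, -2], X=np.ones((2, 1)), names=("a",))
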