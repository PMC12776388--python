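"""Gil-Pelaez CDF inversion, threshold solving, operating points, ROC.

Closed-form oracles: when all lam_i = 1 the statistic is Gaussian; when all
m_i = 0 with a shared lam it is a scaled (central) chi-square; for general
univariate pairs it is an affinely transformed noncentral chi-square, for
which scipy's ncx2 provides an independent exact reference.
"""

import numpy as np
import pytest
from scipy import stats

import cellnp as cp
from cellnp.errors import DegenerateStatisticError
from tests.conftest import gaussian
from tests.test_char_fn import make_pair

PHI_INV_09 = stats.norm.ppf(0.9)


class TestCdfClosedForms:
    def test_gaussian_case_exact(self, equal_var_pair):
        # Z ~ N(-1, 4) under H0
        for z in (-4.0, -1.0, 0.0, 1.563103, 5.0):
            got = cp.cdf_test_statistic(z, equal_var_pair, "H0")
            assert got == pytest.approx(stats.norm.cdf(z, -1.0, 2.0), abs=1e-6)
        assert cp.cdf_test_statistic(0.0, equal_var_pair, "H0") == pytest.approx(
            stats.norm.cdf(0.5), abs=1e-6
        )
        assert cp.cdf_test_statistic(-1.0, equal_var_pair, "H0") == pytest.approx(
            0.5, abs=1e-6
        )

    def test_scaled_chi_square_case_exact(self):
        pair = make_pair(0.0, 4.0)
        # statistic (3/4)chi2_1 is nonnegative: F(0) = 0
        assert cp.cdf_test_statistic(0.0, pair, "H0") == 0.0
        # median: F(0.75 * chi2_1 median) = 0.5
        med = 0.75 * stats.chi2.ppf(0.5, 1)
        assert cp.cdf_test_statistic(med, pair, "H0") == pytest.approx(0.5, abs=1e-6)
        for q in np.linspace(0.02, 0.98, 9):
            z = 0.75 * stats.chi2.ppf(q, 1)
            assert cp.cdf_test_statistic(z, pair, "H0") == pytest.approx(q, abs=1e-6)

    @pytest.mark.parametrize("m,lam,hyp", [
        (0.7, 4.0, "H0"), (0.7, 4.0, "H1"), (-1.2, 0.3, "H0"), (0.4, 2.0, "H1"),
    ])
    def test_univariate_matches_noncentral_chi_square(self, m, lam, hyp):
        pair = make_pair(m, lam)
        # affine map of Z onto a noncentral chi-square, per hypothesis
        if hyp == "H0":
            a, b, c = 1 - 1 / lam, 2 * m / lam, -(m**2) / lam
        else:
            a, b, c = lam - 1, 2 * m * np.sqrt(lam), m**2
        d2 = (b / (2 * a)) ** 2
        g0 = c - b**2 / (4 * a)
        qf_mean = g0 + a * (1 + d2)
        for z in np.linspace(qf_mean - 4.0, qf_mean + 4.0, 9):
            exact = stats.ncx2.cdf((z - g0) / a, 1, d2)
            if a < 0:
                exact = 1.0 - exact
            got = cp.cdf_test_statistic(z, pair, hyp)
            assert got == pytest.approx(exact, abs=1e-6)

    def test_monotone_in_z(self):
        pair = make_pair([0.6, -0.3], [2.0, 0.5])
        zs = np.linspace(-8, 8, 41)
        vals = [cp.cdf_test_statistic(z, pair, "H0") for z in zs]
        assert np.all(np.diff(vals) >= -1e-9)

    def test_degenerate_pair_raises(self):
        h = gaussian([0.0, 1.0], np.diag([1.0, 2.0]))
        pair = cp.canonicalize(h, h)
        with pytest.raises(DegenerateStatisticError):
            cp.cdf_test_statistic(0.0, pair, "H0")


class TestSolveThreshold:
    def test_equal_variance_closed_form(self, equal_var_pair):
        z_th = cp.solve_threshold(equal_var_pair, 0.1)
        assert z_th == pytest.approx(2 * PHI_INV_09 - 1, abs=1e-4)
        assert z_th == pytest.approx(1.563103, abs=1e-4)

    def test_alpha_half_gives_h0_median(self, equal_var_pair):
        assert cp.solve_threshold(equal_var_pair, 0.5) == pytest.approx(-1.0, abs=1e-4)

    def test_threshold_decreases_with_alpha(self):
        pair = make_pair(0.8, 3.0)
        assert cp.solve_threshold(pair, 0.999) < cp.solve_threshold(pair, 0.001)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.4])
    def test_alpha_domain_errors(self, equal_var_pair, alpha):
        with pytest.raises(ValueError):
            cp.solve_threshold(equal_var_pair, alpha)

    @pytest.mark.parametrize("alpha", [0.01, 0.1, 0.5, 0.9])
    def test_achieved_pfa_matches_alpha(self, alpha):
        pair = make_pair([0.5, -0.8], [2.2, 0.4])
        z_th = cp.solve_threshold(pair, alpha)
        pfa = 1.0 - cp.cdf_test_statistic(z_th, pair, "H0")
        assert pfa == pytest.approx(alpha, abs=1e-5)


class TestOperatingPoints:
    def test_equal_variance_detection_probability(self, equal_var_pair):
        z_th = 2 * PHI_INV_09 - 1
        pd = cp.detection_probability(equal_var_pair, z_th)
        # Z ~ N(1, 4) under H1
        assert pd == pytest.approx(stats.norm.sf(PHI_INV_09 - 1.0), abs=1e-6)
        assert pd == pytest.approx(0.389130, abs=1e-4)

    def test_pd_saturates_at_low_threshold(self, equal_var_pair):
        assert cp.detection_probability(equal_var_pair, -60.0) == pytest.approx(1.0)

    def test_bivariate_equal_variance_closed_form(self):
        h0 = gaussian([0.0, 0.0], np.eye(2))
        h1 = gaussian([1.0, 1.0], np.eye(2))
        op = cp.operating_point(h0, h1, 0.1)
        # effect size ||m|| = sqrt(2): P_D = Phi(sqrt(2) - Phi^{-1}(0.9))
        assert op.pd == pytest.approx(stats.norm.cdf(np.sqrt(2) - PHI_INV_09), abs=1e-6)
        assert op.pd == pytest.approx(0.552813, abs=1e-4)
        assert op.pfa == pytest.approx(0.1, abs=1e-5)
        assert op.pm == pytest.approx(1.0 - op.pd)

    def test_identical_hypotheses_raise(self):
        h = gaussian(0.0, 1.0)
        with pytest.raises(DegenerateStatisticError):
            cp.operating_point(h, h, 0.1)

    def test_univariate_worked_example(self):
        op = cp.operating_point(gaussian(0.0, 1.0), gaussian(1.0, 1.0), 0.1)
        assert op.pd == pytest.approx(0.389130, abs=1e-4)

    def test_degenerate_coordinate_invariance(self):
        """Appending an uninformative coordinate changes nothing."""
        h0 = gaussian([0.0], [[1.0]])
        h1 = gaussian([0.9], [[2.1]])
        h0p = gaussian([0.0, 3.0], np.diag([1.0, 1.7]))
        h1p = gaussian([0.9, 3.0], np.diag([2.1, 1.7]))
        for alpha in (0.05, 0.3):
            op1 = cp.operating_point(h0, h1, alpha)
            op2 = cp.operating_point(h0p, h1p, alpha)
            assert op2.pd == pytest.approx(op1.pd, abs=1e-6)
            assert op2.pfa == pytest.approx(op1.pfa, abs=1e-6)

    def test_affine_invariance(self):
        """Invertible affine re-parameterization of the raw data leaves every
        operating point unchanged (the LRT is a function of the density
        ratio only)."""
        rng = np.random.default_rng(17)
        h0 = gaussian([0.2, -0.1], [[1.0, 0.3], [0.3, 0.8]])
        h1 = gaussian([1.0, 0.5], [[1.5, -0.2], [-0.2, 2.0]])
        base = cp.operating_point(h0, h1, 0.1)
        for _ in range(4):
            amat = rng.normal(size=(2, 2)) + 2 * np.eye(2)
            bvec = rng.normal(size=2)
            t0 = gaussian(amat @ h0.mean + bvec, amat @ h0.cov @ amat.T)
            t1 = gaussian(amat @ h1.mean + bvec, amat @ h1.cov @ amat.T)
            op = cp.operating_point(t0, t1, 0.1)
            assert op.pd == pytest.approx(base.pd, abs=1e-6)
            assert op.pfa == pytest.approx(base.pfa, abs=1e-6)


class TestROC:
    def test_equal_variance_closed_form_points(self):
        h0, h1 = gaussian(0.0, 1.0), gaussian(1.0, 1.0)
        curve = cp.roc_curve(h0, h1, [0.1, 0.5])
        assert curve.pd_values[0] == pytest.approx(0.389130, abs=1e-4)
        # at alpha = 0.5 the threshold is the H0 median: P_D = Phi(m) = Phi(1)
        assert curve.pd_values[1] == pytest.approx(stats.norm.cdf(1.0), abs=1e-4)

    def test_curve_monotone_and_above_diagonal(self, truth_models):
        h0 = truth_models[("WT", "h0")].marginal([0])
        h1 = truth_models[("WT", "h1")].marginal([0])
        grid = np.linspace(0.02, 0.98, 25)
        curve = cp.roc_curve(h0, h1, grid)
        assert np.all(np.diff(curve.pd_values) >= -1e-6)
        assert np.all(curve.pd_values >= grid - 1e-4)

    def test_roc_concavity(self):
        pair_h0 = gaussian(0.0, 1.0)
        pair_h1 = gaussian(0.8, 2.5)
        grid = np.linspace(0.05, 0.95, 19)
        curve = cp.roc_curve(pair_h0, pair_h1, grid)
        second_diff = np.diff(curve.pd_values, 2)
        assert np.all(second_diff <= 1e-4)

    def test_endpoint_limits(self):
        h0, h1 = gaussian(0.0, 1.0), gaussian(1.5, 1.2)
        curve = cp.roc_curve(h0, h1, [1e-5, 1 - 1e-5])
        assert curve.pd_values[0] < 0.05
        assert curve.pd_values[-1] > 0.9999

    def test_grid_validation(self):
        h0, h1 = gaussian(0.0, 1.0), gaussian(1.0, 1.0)
        with pytest.raises(ValueError):
            cp.roc_curve(h0, h1, [0.0, 0.5])
        with pytest.raises(ValueError):
            cp.roc_curve(h0, h1, [0.5, 0.2])


class TestPfaAtPd:
    def test_inverse_of_closed_form(self):
        h0, h1 = gaussian(0.0, 1.0), gaussian(1.0, 1.0)
        alpha = cp.pfa_at_pd(h0, h1, stats.norm.cdf(1.0))
        assert alpha == pytest.approx(0.5, abs=1e-3)
        alpha2 = cp.pfa_at_pd(h0, h1, 0.389130)
        assert alpha2 == pytest.approx(0.1, abs=1e-3)

    def test_round_trip_with_operating_point(self, truth_models):
        h0 = truth_models[("WT", "h0")].marginal([0])
        h1 = truth_models[("WT", "h1")].marginal([0])
        alpha = cp.pfa_at_pd(h0, h1, 0.8)
        op = cp.operating_point(h0, h1, alpha)
        assert op.pd == pytest.approx(0.8, abs=1e-4)

    def test_saturation_with_huge_separation(self):
        h0, h1 = gaussian(0.0, 1.0), gaussian(12.0, 1.0)
        assert cp.pfa_at_pd(h0, h1, 0.9) <= 1e-5

    def test_target_domain_errors(self):
        h0, h1 = gaussian(0.0, 1.0), gaussian(1.0, 1.0)
        with pytest.raises(ValueError):
            cp.pfa_at_pd(h0, h1, 0.0)
        with pytest.raises(ValueError):
            cp.pfa_at_pd(h0, h1, 1.0)


class TestNPDominance:
    def test_bivariate_roc_dominates_marginals(self, truth_models):
        """Using both time points cannot hurt: the joint LRT is at least as
        powerful as either marginal test at every false-alarm level."""
        h0, h1 = truth_models[("WT", "h0")], truth_models[("WT", "h1")]
        grid = np.linspace(0.05, 0.95, 10)
        joint = cp.roc_curve(h0, h1, grid).pd_values
        for idx in ([0], [1]):
            marg = cp.roc_curve(h0.marginal(idx), h1.marginal(idx), grid).pd_values
            assert np.all(joint >= marg - 1e-4)
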