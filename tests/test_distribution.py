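"""Core hcMB-III distribution: density, cdf, quantile, rng, hazard, modes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import kstest

import hcmb3 as h
from hcmb3.distribution import linear_cdf

GRID = np.linspace(0.05, np.pi - 0.05, 61)
PARAM_GRID = [(a, b, g) for a in (0.5, 1, 2, 4, 8)
              for b in (0.5, 1, 2, 4, 8) for g in (0.5, 1, 2, 4, 8)]


class TestPdf:
    def test_hand_value_at_half_pi(self):
        # (1/2)*1*1*sec^2(pi/4)*1*(1+1)^(-2) = 1/4
        assert h.pdf(np.pi / 2, (1, 1, 1)) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("params", [(2, 3, 4), (0.5, 0.5, 0.5), (8, 0.5, 2), (1, 8, 1)])
    def test_normalizes_to_one(self, params):
        total, err = quad(lambda th: h.pdf(th, params), 0, np.pi, limit=300)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_cdf_derivative(self):
        p = (1.5, 3.5, 3.5)
        eps = 1e-6
        num = (h.cdf(GRID + eps, p) - h.cdf(GRID - eps, p)) / (2 * eps)
        assert np.allclose(num, h.pdf(GRID, p), atol=1e-6)

    def test_boundary_limit(self):
        assert h.pdf(0.0, (2, 3, 4)) == 0.0  # alpha*beta > gamma: decays
        # alpha*beta == gamma: finite limit (alpha*beta/2) * gamma^(-alpha/gamma - 1)
        assert h.pdf(0.0, (1, 2, 2)) == pytest.approx(0.5 * 2 * 2 ** (-1.5), rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            h.pdf(3.5, (1, 1, 1))
        with pytest.raises(ValueError):
            h.pdf(-0.1, (1, 1, 1))
        with pytest.raises(ValueError):
            h.pdf(1.0, (1, -1, 1))
        with pytest.raises(ValueError):
            h.pdf(np.nan, (1, 1, 1))


class TestCdf:
    def test_hand_value_and_limits(self):
        assert h.cdf(np.pi / 2, (1, 1, 1)) == pytest.approx(0.5, abs=1e-12)
        assert h.cdf(0.0, (2, 3, 4)) == 0.0
        assert h.cdf(np.pi - 1e-9, (2, 3, 4)) == pytest.approx(1.0, abs=1e-6)

    def test_projection_identity(self):
        # G(theta) is exactly the linear modified Burr-III cdf at tan(theta/2)
        p = (2.7, 6.6, 6.3)
        assert np.array_equal(h.cdf(GRID, p), linear_cdf(np.tan(GRID / 2), p))

    @given(st.floats(0.01, np.pi - 0.01), st.floats(0.01, np.pi - 0.01))
    def test_monotone(self, th1, th2):
        lo, hi = sorted((th1, th2))
        assert h.cdf(lo, (2, 3, 4)) <= h.cdf(hi, (2, 3, 4)) + 1e-15


class TestQuantile:
    def test_median_hand_inversion(self):
        assert h.quantile(0.5, (1, 1, 1)) == pytest.approx(np.pi / 2, abs=1e-12)

    @pytest.mark.parametrize("params", [(1, 1, 1), (2, 3, 4), (4, 3, 4), (0.5, 8, 0.5)])
    def test_round_trip(self, params):
        u = np.array([1e-6, 1e-3, 0.1, 0.5, 0.9, 1 - 1e-3, 1 - 1e-6])
        assert np.allclose(h.cdf(h.quantile(u, params), params), u, atol=1e-10)
        theta = np.linspace(0.2, 3.0, 30)
        assert np.allclose(h.quantile(h.cdf(theta, (4, 3, 4)), (4, 3, 4)), theta, atol=1e-9)

    def test_against_bisection_oracle(self):
        root = brentq(lambda th: h.cdf(th, (2, 3, 4)) - 0.9, 1e-9, np.pi - 1e-9, xtol=1e-13)
        assert h.quantile(0.9, (2, 3, 4)) == pytest.approx(root, abs=1e-9)

    def test_domain_errors(self):
        for u in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                h.quantile(u, (1, 1, 1))


class TestRng:
    def test_deterministic_under_seed(self):
        a = h.rng(10, (2, 3, 4), seed=5)
        b = h.rng(10, (2, 3, 4), seed=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, h.rng(10, (2, 3, 4), seed=6))

    def test_follows_model_law(self):
        s = h.rng(50_000, (2, 3, 4), seed=11)
        d = kstest(s, lambda x: h.cdf(x, (2, 3, 4))).statistic
        assert d < 1.63 / np.sqrt(50_000)  # 1% asymptotic critical value

    def test_moments_match_quadrature(self):
        s = h.rng(50_000, (2, 3, 4), seed=13)
        a1 = h.trig_moment(1, (2, 3, 4)).alpha_p
        emp = np.cos(s)
        assert abs(emp.mean() - a1) < 3 * emp.std(ddof=1) / np.sqrt(s.size)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            h.rng(0, (1, 1, 1), seed=0)


class TestHazard:
    def test_identity_with_pdf_over_survival(self):
        p = (2, 3, 4)
        expected = h.pdf(GRID, p) / (1 - h.cdf(GRID, p))
        assert np.allclose(h.hazard(GRID, p), expected, atol=1e-10)

    def test_hand_value(self):
        assert h.hazard(np.pi / 2, (1, 1, 1)) == pytest.approx(0.5, abs=1e-12)

    def test_increasing_regime(self):
        # one of the documented hazard regimes: monotone increasing
        vals = h.hazard(np.linspace(0.1, 3.0, 300), (4, 8, 0.5))
        assert np.all(np.diff(vals) > 0)

    def test_infinite_where_survival_vanishes(self):
        assert np.isinf(h.hazard(np.pi - 1e-12, (2, 3, 4)))


class TestFamilies:
    def test_burr3_is_gamma_one_submodel(self):
        p3 = h.ProjectedFamily("hcburr3", (2.0, 3.0))
        full = h.cdf(GRID, (2.0, 3.0, 1.0))
        assert np.allclose(h.family_cdf(GRID, p3), full, atol=1e-12)

    def test_inverse_weibull_limit_small_gamma(self):
        g = 1e-8
        lim = np.exp(-2.0 * np.tan(GRID / 2) ** (-3.0))
        assert np.allclose(h.cdf(GRID, (2.0, 3.0, g)), lim, atol=1e-6)

    def test_loglogistic_hand_value_and_collapse(self):
        assert h.family_cdf(np.pi / 2, h.ProjectedFamily("hcll", (1.0, 1.0))) == pytest.approx(0.5)
        # hcMB3 with alpha == gamma is log-logistic with scale alpha^(1/beta)
        a, b = 2.5, 3.0
        ll = h.ProjectedFamily("hcll", (a ** (1 / b), b))
        assert np.allclose(h.cdf(GRID, (a, b, a)), h.family_cdf(GRID, ll), atol=1e-12)

    def test_giw_is_proper_cdf(self):
        fam = h.ProjectedFamily("hcgiw", (0.8, 1.7, 0.9))
        vals = h.family_cdf(GRID, fam)
        assert np.all(np.diff(vals) > 0)
        assert h.family_cdf(np.pi - 1e-8, fam) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("tag,params", [("hcgamma", (5.7, 0.19)), ("hcburr12", (4.4, 0.95))])
    def test_two_parameter_projections_are_proper(self, tag, params):
        fam = h.ProjectedFamily(tag, params)
        grid = np.linspace(1e-4, np.pi - 1e-8, 500)
        vals = h.family_cdf(grid, fam)
        assert np.all(np.diff(vals) >= 0)
        assert vals[0] < 1e-3 and vals[-1] > 1 - 1e-3
        # density integrates to one over the half circle
        total = quad(lambda th: h.family_pdf(th, fam), 0, np.pi, limit=300)[0]
        assert total == pytest.approx(1.0, abs=1e-7)

    def test_unknown_tag_raises(self):
        with pytest.raises(KeyError):
            h.family_cdf(1.0, h.ProjectedFamily("nope", (1.0,)))
        with pytest.raises(ValueError):
            h.family_cdf(1.0, h.ProjectedFamily("hcll", (1.0, 1.0, 1.0)))


class TestModes:
    def test_unimodal_case_dominates_grid(self):
        modes = h.find_modes((2, 3, 4))
        assert len(modes) == 1
        theta_star, dens = modes[0]
        grid = np.linspace(1e-6, np.pi - 1e-6, 4096)
        assert dens >= h.pdf(grid, (2, 3, 4)).max() - 1e-10

    def test_modes_are_stationary_points(self):
        from hcmb3.distribution import _dlogpdf_dtheta
        for params in [(2, 3, 4), (1.5, 3.5, 3.5)]:
            for theta_star, _ in h.find_modes(params):
                assert abs(_dlogpdf_dtheta(theta_star, params)) < 1e-6

    def test_stationarity_function_matches_numeric_derivative(self):
        from hcmb3.distribution import _dlogpdf_dtheta
        eps = 1e-7
        for params in [(2, 3, 4), (0.6, 0.9, 2.0)]:
            num = (h.logpdf(GRID + eps, params) - h.logpdf(GRID - eps, params)) / (2 * eps)
            assert np.allclose(_dlogpdf_dtheta(GRID, params), num, atol=1e-5)

    @pytest.mark.parametrize("params", [(2, 3, 4), (0.3, 1.0, 0.3), (1.5, 3.5, 3.5)])
    def test_count_matches_brute_force_grid(self, params):
        dense = np.linspace(1e-6, np.pi - 1e-6, 100_000)
        dens = h.pdf(dense, params)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        assert len(h.find_modes(params)) == int(interior.sum())


def test_normalization_over_parameter_grid():
    # full 5x5x5 shape grid; tight tolerances ride out the integrable
    # boundary singularities (theta -> 0 when alpha*beta < gamma, theta -> pi
    # when beta < 1)
    import warnings
    from scipy.integrate import IntegrationWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        for params in PARAM_GRID:
            total = quad(lambda th: h.pdf(th, params), 0, np.pi,
                         limit=1000, epsabs=1e-12, epsrel=1e-12)[0]
            assert total == pytest.approx(1.0, abs=1e-8), params
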