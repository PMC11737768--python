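"""Core distribution functions: exact identities, limits, and frozen oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from hleird import (
    HleirdParams,
    cdf,
    hazard,
    median,
    mgf,
    order_statistic_pdf,
    pdf,
    quantile,
    random_sample,
    sf,
    shape_measures,
)

P111 = HleirdParams(1.0, 1.0, 1.0)
P222 = HleirdParams(2.0, 2.0, 2.0)

# oracle: direct high-precision evaluation of the density formula at x=1,
# (sigma, alpha, lam) = (1,1,1): 4*exp(-1)/(1 + (1 - exp(-1)))**2
PDF_AT_1_111 = 0.5524093728035459


class TestCdfPdf:
    def test_cdf_limits(self, param_grid):
        for p in param_grid:
            assert cdf(1e12, p) == pytest.approx(1.0, abs=1e-12)
            assert cdf(0.0, p) == 0.0
            assert cdf(-3.0, p) == 0.0

    def test_cdf_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            cdf(np.inf, P111)
        with pytest.raises(ValueError):
            quantile(1.5, P111)

    def test_params_must_be_positive(self):
        for bad in [(0.0, 1, 1), (1, -2, 1), (1, 1, np.nan)]:
            with pytest.raises(ValueError):
                HleirdParams(*bad)

    def test_pdf_frozen_value(self):
        assert pdf(1.0, P111) == pytest.approx(PDF_AT_1_111, rel=1e-12)

    def test_pdf_normalizes(self, param_grid):
        for p in param_grid:
            total, _ = quad(lambda x: pdf(x, p), 0, np.inf, limit=300)
            assert total == pytest.approx(1.0, abs=1e-7)

    def test_pdf_is_cdf_derivative(self):
        x, h = 2.0, 1e-6
        num = (cdf(x + h, P111) - cdf(x - h, P111)) / (2 * h)
        assert pdf(x, P111) == pytest.approx(num, abs=1e-6)

    def test_sf_complements_cdf(self, param_grid):
        xs = np.array([0.3, 0.9, 1.7, 4.2, 11.0])
        for p in param_grid:
            np.testing.assert_allclose(sf(xs, p) + cdf(xs, p), 1.0, atol=1e-14)

    def test_hazard_is_pdf_over_sf(self, param_grid):
        xs = np.array([0.5, 1.0, 2.5, 6.0])
        for p in param_grid:
            np.testing.assert_allclose(
                hazard(xs, p) * sf(xs, p), pdf(xs, p), rtol=1e-12
            )

    def test_identifiability_ridge_exact(self):
        """cdf/pdf depend on (alpha, lam) only through theta: hard equality."""
        xs = np.array([0.4, 1.0, 2.3, 7.7])
        base = HleirdParams(1.3, 2.0, 1.5)
        for c in (0.5, 2.0, 4.0):
            other = HleirdParams(1.3, c * 2.0, 1.5 / c)
            assert np.all(cdf(xs, base) == cdf(xs, other))
            assert np.all(pdf(xs, base) == pdf(xs, other))

    def test_monotone_in_parameters(self):
        """F increases with either shape (u = b^theta shrinks, b < 1) and
        decreases with the scale sigma."""
        x = 1.5
        f0 = cdf(x, HleirdParams(1.0, 1.0, 1.0))
        assert cdf(x, HleirdParams(1.0, 1.4, 1.0)) > f0
        assert cdf(x, HleirdParams(1.0, 1.0, 1.4)) > f0
        assert cdf(x, HleirdParams(1.4, 1.0, 1.0)) < f0


class TestQuantile:
    def test_median_against_bisection(self):
        root = brentq(lambda x: cdf(x, P222) - 0.5, 0.1, 50.0, xtol=1e-13)
        assert quantile(0.5, P222) == pytest.approx(root, abs=1e-10)
        assert quantile(0.5, P222) == pytest.approx(1.6745744754693532, rel=1e-10)

    def test_median_closed_form(self, param_grid):
        for p in param_grid:
            closed = p.sigma * (-np.log(1.0 - (1.0 / 3.0) ** (1.0 / p.theta))) ** -0.5
            assert median(p) == pytest.approx(closed, rel=1e-12)

    def test_roundtrip(self, param_grid, rng):
        probs = rng.uniform(1e-6, 1 - 1e-6, size=1000)
        for p in param_grid:
            np.testing.assert_allclose(cdf(quantile(probs, p), p), probs, atol=1e-9)

    def test_strictly_increasing(self):
        q = quantile(np.linspace(0.01, 0.99, 200), P222)
        assert np.all(np.diff(q) > 0)

    def test_scale_family(self, param_grid):
        probs = np.array([0.1, 0.5, 0.9])
        for p in param_grid:
            scaled = HleirdParams(3.0 * p.sigma, p.alpha, p.lam)
            np.testing.assert_allclose(
                quantile(probs, scaled), 3.0 * quantile(probs, p), rtol=1e-12
            )

    @settings(derandomize=True, max_examples=60)
    @given(
        prob=st.floats(1e-6, 1 - 1e-6),
        theta=st.floats(0.05, 30.0),
        sigma=st.floats(0.05, 20.0),
    )
    def test_roundtrip_property(self, prob, theta, sigma):
        p = HleirdParams.from_theta(theta, sigma)
        assert cdf(quantile(prob, p), p) == pytest.approx(prob, abs=1e-9)


class TestSampling:
    def test_deterministic_for_seed(self):
        a = random_sample(100, P111, seed=7).values
        b = random_sample(100, P111, seed=7).values
        assert np.array_equal(a, b)

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            random_sample(0, P111, seed=1)

    def test_empirical_cdf_converges(self):
        xs = random_sample(100_000, P111, seed=3).sorted_values
        i = np.arange(1, xs.size + 1)
        F = cdf(xs, P111)
        d = max(np.max(i / xs.size - F), np.max(F - (i - 1) / xs.size))
        assert d < 0.01  # asymptotic 1% K-S band at n = 1e5 is ~0.0043

    def test_sample_median_matches_quantile(self):
        xs = random_sample(100_000, P222, seed=11).values
        assert np.median(xs) == pytest.approx(quantile(0.5, P222), abs=0.02)


class TestOrderStatistics:
    def test_single_draw_is_pdf(self):
        xs = np.array([0.5, 1.0, 2.0])
        np.testing.assert_allclose(order_statistic_pdf(1, 1, xs, P111), pdf(xs, P111))

    def test_normalization(self):
        total, _ = quad(lambda x: order_statistic_pdf(2, 5, x, P111), 0, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_minimum_formula_matches_generic(self):
        # smallest order statistic of m=3: generic F^(k-1) (1-F)^(m-k) f form
        x = 1.0
        generic = 3 * sf(x, P111) ** 2 * pdf(x, P111)
        assert order_statistic_pdf(1, 3, x, P111) == pytest.approx(generic, rel=1e-12)

    def test_max_dominates_min(self):
        e_min, _ = quad(lambda x: x * order_statistic_pdf(1, 4, x, P111), 0, np.inf, limit=300)
        e_max, _ = quad(lambda x: x * order_statistic_pdf(4, 4, x, P111), 0, np.inf, limit=300)
        assert e_max > e_min

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            order_statistic_pdf(0, 3, 1.0, P111)
        with pytest.raises(ValueError):
            order_statistic_pdf(4, 3, 1.0, P111)


class TestShapeMeasures:
    @pytest.mark.parametrize(
        "params, galton, moors",
        [
            ((2.0, 2.0, 2.0), 0.106396, 1.27979),
            ((0.5, 0.5, 0.5), 0.728443, 4.52466),
            ((1.0, 1.0, 1.0), 0.300056, 1.54687),
            ((3.5, 3.5, 3.5), 0.030862, 1.24621),
        ],
    )
    def test_published_table(self, params, galton, moors):
        sm = shape_measures(HleirdParams(*params))
        assert sm.galton_skewness == pytest.approx(galton, abs=1e-5)
        assert sm.moors_kurtosis == pytest.approx(moors, abs=1e-5)

    def test_depends_only_on_theta(self):
        """sigma-invariant; any (alpha, lam) split with the same product agrees."""
        ref = shape_measures(HleirdParams(1.0, 1.0, 1.0))
        for trip in [(0.5, 0.5, 2.0), (2.0, 0.5, 2.0), (7.0, 4.0, 0.25)]:
            sm = shape_measures(HleirdParams(*trip))
            assert sm.galton_skewness == pytest.approx(ref.galton_skewness, rel=1e-12)
            assert sm.moors_kurtosis == pytest.approx(ref.moors_kurtosis, rel=1e-12)


class TestMgf:
    def test_diverges_for_positive_argument(self):
        with pytest.raises(ValueError):
            mgf(0.1, P111)

    def test_laplace_transform_values(self):
        assert mgf(0.0, P111) == pytest.approx(1.0, abs=1e-8)
        m1 = mgf(-0.5, P111)
        m2 = mgf(-1.0, P111)
        assert 0 < m2 < m1 < 1.0
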