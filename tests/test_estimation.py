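"""Likelihood plumbing, the five estimators, and the identifiability ridge."""

import math

import numpy as np
import pandas as pd
import pytest

from hleird import HleirdParams, fit_cvm, fit_lse, fit_mle, fit_mps, fit_wlse, random_sample
from hleird.data import LifetimeSample
from hleird.estimation import (
    HalfLogisticEIRModel,
    cdf_param_derivatives,
    cvm_criterion,
    ecdf_positions,
    lse_criterion,
    mps_mean_log_spacing,
    mps_spacings,
    neg_log_likelihood,
    score,
    score_and_information,
    wlse_criterion,
)
from hleird.distribution import logpdf, quantile

P111 = HleirdParams(1.0, 1.0, 1.0)
PAPER_POINT_D1 = HleirdParams(sigma=3.6338, alpha=0.7691, lam=12.5518)


@pytest.fixture(scope="module")
def sim50():
    return random_sample(50, P111, seed=424242)


class TestLikelihood:
    def test_nll_is_sum_of_logpdf(self, fibers_20mm):
        direct = -float(np.sum(logpdf(fibers_20mm.values, PAPER_POINT_D1)))
        assert neg_log_likelihood(PAPER_POINT_D1, fibers_20mm) == pytest.approx(
            direct, abs=1e-10
        )

    def test_single_observation(self):
        nll = neg_log_likelihood(P111, LifetimeSample(np.array([1.0])))
        assert nll == pytest.approx(-math.log(0.5524093728035459), rel=1e-10)

    def test_infeasible_point_is_inf_not_crash(self, fibers_20mm):
        # overflow region: reported as an infeasible (+inf) point, not an exception
        assert neg_log_likelihood(HleirdParams(1e300, 1.0, 1.0), fibers_20mm) == np.inf
        # a merely terrible point stays finite
        assert np.isfinite(neg_log_likelihood(HleirdParams(1e-6, 1.0, 1.0), fibers_20mm))


class TestScoreAndInformation:
    def test_score_matches_finite_differences(self, sim50):
        p = P111
        g = score(p, sim50)
        vals = np.array([p.sigma, p.alpha, p.lam])
        for j in range(3):
            h = 1e-6
            up, dn = vals.copy(), vals.copy()
            up[j] += h
            dn[j] -= h
            num = (
                -neg_log_likelihood(HleirdParams(*up), sim50)
                + neg_log_likelihood(HleirdParams(*dn), sim50)
            ) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-5)

    def test_information_symmetric(self, sim50):
        _, info = score_and_information(P111, sim50)
        assert np.array_equal(info, info.T)

    def test_ridge_is_null_direction(self, sim50):
        """l depends on (theta, sigma) only, so the directional derivative
        along (0, alpha, -lam) vanishes identically."""
        p = HleirdParams(1.2, 0.8, 2.5)
        g = score(p, sim50)
        assert abs(g[1] * p.alpha - g[2] * p.lam) < 1e-8 * max(1.0, abs(g[1] * p.alpha))


class TestCdfParamDerivatives:
    def test_matches_finite_differences(self):
        xs = np.array([0.5, 1.0, 2.0, 4.0])
        p = P111
        from hleird.distribution import cdf

        d = cdf_param_derivatives(xs, p)
        vals = np.array([p.sigma, p.alpha, p.lam])
        for j in range(3):
            h = 1e-6
            up, dn = vals.copy(), vals.copy()
            up[j] += h
            dn[j] -= h
            num = (cdf(xs, HleirdParams(*up)) - cdf(xs, HleirdParams(*dn))) / (2 * h)
            np.testing.assert_allclose(d[j], num, rtol=1e-6, atol=1e-10)

    def test_ridge_identity_and_signs(self):
        xs = np.array([0.7, 1.3, 3.0])
        p = HleirdParams(1.5, 2.0, 0.6)
        d = cdf_param_derivatives(xs, p)
        np.testing.assert_allclose(p.alpha * d[1], p.lam * d[2], rtol=1e-12)
        assert np.all(d[0] < 0)  # F strictly decreasing in sigma
        assert np.all(d[1] > 0)  # and increasing in each shape
        assert np.all(d[2] > 0)


class TestRidgeInvariance:
    def test_all_objectives_invariant_along_ridge(self, fibers_20mm):
        objectives = [
            neg_log_likelihood,
            lse_criterion,
            wlse_criterion,
            cvm_criterion,
            mps_mean_log_spacing,
        ]
        base = HleirdParams(3.0, 2.0, 4.0)
        for obj in objectives:
            ref = obj(base, fibers_20mm)
            for c in (0.5, 2.0):  # exact splits: c*alpha and lam/c are exact binary scalings
                alt = HleirdParams(3.0, c * 2.0, 4.0 / c)
                assert obj(alt, fibers_20mm) == ref
            alt10 = HleirdParams(3.0, 10.0 * 2.0, 4.0 / 10.0)
            assert obj(alt10, fibers_20mm) == pytest.approx(ref, rel=5e-13)


class TestEcdfPositions:
    def test_positions_and_weights(self):
        tbl = ecdf_positions(5)
        assert np.all(np.diff(tbl["lse_position"]) > 0)
        assert np.all(np.diff(tbl["cvm_position"]) > 0)
        assert np.all(tbl["wls_weight"] > 0)
        # weight formula at i=1, n=5: 36*7/5
        assert tbl["wls_weight"].iloc[0] == pytest.approx(36.0 * 7.0 / 5.0)


class TestDistanceFits:
    def test_perfect_fit_has_zero_criterion(self):
        p = HleirdParams(2.0, 1.0, 3.0)
        n = 40
        xs = quantile(np.arange(1, n + 1) / (n + 1.0), p)
        sample = LifetimeSample(xs)
        assert lse_criterion(p, sample) == pytest.approx(0.0, abs=1e-25)
        assert wlse_criterion(p, sample) == pytest.approx(0.0, abs=1e-20)
        res = fit_lse(sample)
        assert res.objective_at_optimum < 1e-12
        assert res.theta == pytest.approx(p.theta, rel=1e-2)
        assert res.sigma == pytest.approx(p.sigma, rel=1e-3)

    def test_wlse_criterion_nonnegative(self, fibers_20mm):
        assert wlse_criterion(P111, fibers_20mm) > 0

    def test_cvm_criterion_floor(self, fibers_20mm):
        n = fibers_20mm.n
        assert cvm_criterion(P111, fibers_20mm) >= 1.0 / (12.0 * n)
        res = fit_cvm(fibers_20mm)
        assert res.objective_at_optimum >= 1.0 / (12.0 * n)

    def test_lse_cvme_agree_at_large_n(self):
        sample = random_sample(5000, HleirdParams(1.0, 1.0, 1.0), seed=5)
        a = fit_lse(sample)
        b = fit_cvm(sample)
        assert abs(a.theta - b.theta) < 0.02 * max(1.0, a.theta)
        assert abs(a.sigma - b.sigma) < 0.02


class TestMps:
    def test_spacings_telescope_to_one(self, fibers_20mm):
        for p in (P111, HleirdParams(3.6, 1.0, 10.0)):
            assert np.sum(mps_spacings(p, fibers_20mm)) == pytest.approx(1.0, abs=1e-12)

    def test_fit_survives_ties(self, fibers_20mm):
        # the fiber data contain exact ties (2.301, 2.301 etc.)
        res = fit_mps(fibers_20mm)
        assert np.isfinite(res.objective_at_optimum)
        assert res.converged

    def test_parameter_recovery(self):
        truth = HleirdParams.from_theta(1.0, 1.0)
        sample = random_sample(2000, truth, seed=99)
        res = fit_mps(sample)
        assert res.theta == pytest.approx(1.0, abs=0.15)
        assert res.sigma == pytest.approx(1.0, abs=0.05)


class TestMle:
    def test_recovery_within_wald_band(self):
        truth = HleirdParams.from_theta(2.0, 1.0)
        sample = random_sample(5000, truth, seed=2024)
        res = fit_mle(sample)
        se = res.std_errors_identifiable
        assert abs(res.theta - 2.0) < 3.0 * se["theta"]
        assert abs(res.sigma - 1.0) < 3.0 * se["sigma"]

    def test_gradient_vanishes_at_optimum(self, fibers_20mm):
        res = fit_mle(fibers_20mm)
        g = score(res.params, fibers_20mm)
        # ridge direction excluded: check the identifiable directions
        d_theta = g[2] / res.params.alpha  # dl/dtheta for the alpha-split
        assert abs(d_theta) < 1e-4
        assert abs(g[0]) < 1e-3

    def test_intervals_contain_estimates(self, fibers_20mm):
        res = fit_mle(fibers_20mm)
        for name, (lo, hi) in res.confidence_intervals.items():
            value = getattr(res, name)
            assert lo <= value <= hi

    def test_free_mode_requires_start_and_stays_on_ridge(self, fibers_20mm):
        with pytest.raises(ValueError):
            fit_mle(fibers_20mm, free_shapes=True)
        start = HleirdParams(3.6, 1.0, 10.0)
        res = fit_mle(fibers_20mm, start=start, free_shapes=True)
        constrained = fit_mle(fibers_20mm)
        assert res.llf == pytest.approx(constrained.llf, abs=1e-5)

    def test_consistency_over_n(self):
        """Squared error of (theta, sigma) shrinks with n (small seeded check)."""
        truth = HleirdParams(0.5, 0.5, 1.0)
        errs = []
        for n in (20, 150):
            sq = []
            for rep in range(60):
                s = random_sample(n, truth, seed=1000 + rep)
                r = fit_mle(s, start=truth, free_shapes=True)
                sq.append((r.sigma - truth.sigma) ** 2)
            errs.append(np.mean(sq))
        assert errs[1] < errs[0]


class TestModelObject:
    def test_from_dataframe_and_summary(self, fibers_20mm):
        df = pd.DataFrame({"gpa": fibers_20mm.values})
        model = HalfLogisticEIRModel.from_dataframe(df, "gpa")
        res = model.fit()
        text = res.summary()
        assert "MLE" in text and "theta" in text and "AIC" in text

    def test_unknown_method_rejected(self, fibers_20mm):
        with pytest.raises(ValueError):
            HalfLogisticEIRModel(fibers_20mm).fit(method="magic")

    def test_fit_all_covers_methods(self, fibers_10mm):
        results = HalfLogisticEIRModel(fibers_10mm).fit_all()
        assert set(results) == {"mle", "lse", "wlse", "cvme", "mps"}
        assert all(r.converged for r in results.values())
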