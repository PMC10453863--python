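import math

import numpy as np
import pytest

from rtentropy import (
    BANS,
    BITS,
    NATS,
    Exponential,
    RTSample,
    cre_density,
    cre_empirical,
    cre_exponential_analytic,
    cre_from_survivor,
    cumulative_hazard,
    hazard_in_bits,
    icre,
    icre_from_sample,
    icre_slope,
)
from rtentropy.curves import FunctionCurve
from rtentropy.exceptions import EstimatorError, ParameterError, UsageError, ValidationError

# hand-computed plug-in CRE of {1,2,3}: (-2/3 ln 2/3) + (-1/3 ln 1/3)
CRE_123 = 2 / 3 * math.log(3 / 2) + 1 / 3 * math.log(3.0)


class TestCREQuadrature:
    @pytest.mark.parametrize("lam", [0.25, 0.5, 0.9, 2.0])
    def test_exponential_closed_form(self, lam):
        # CRE of Exp(lam) equals its mean 1/lam (nats)
        t = np.arange(0.0, 30.0 / lam + 0.001, 0.001)
        surv = Exponential(lam).survivor(t)
        res = cre_from_survivor(surv, base=NATS)
        assert res.value == pytest.approx(1 / lam, rel=1e-3)

    def test_uniform_closed_form(self):
        # S(t) = 1 - t/a on [0, a]: CRE = a/4
        a = 4.0
        t = np.linspace(0.0, a, 4001)
        surv = FunctionCurve(t, 1 - t / a, "survivor")
        assert cre_from_survivor(surv).value == pytest.approx(a / 4, rel=1e-3)

    def test_point_mass_has_zero_entropy(self):
        surv = FunctionCurve(np.array([0.0, 5.0, 5.001, 10.0]),
                             np.array([1.0, 1.0, 0.0, 0.0]), "survivor")
        assert cre_from_survivor(surv).value == pytest.approx(0.0, abs=1e-3)

    def test_integration_bounds_are_honoured(self):
        t = np.arange(0.0, 30.001, 0.001)
        surv = Exponential(1.0).survivor(t)
        full = cre_from_survivor(surv)
        half = cre_from_survivor(surv, lower=0.0, upper=1.0)
        assert half.value < full.value
        assert (half.lower, half.upper) == (0.0, 1.0)

    def test_rejects_wrong_kind_and_invalid_values(self):
        with pytest.raises(UsageError):
            cre_from_survivor(FunctionCurve(np.array([0.0, 1.0]),
                                            np.array([0.0, 0.5]), "cdf"))
        bad = FunctionCurve(np.array([0.0, 1.0]), np.array([1.0, 0.5]), "survivor")
        object.__setattr__(bad, "values", np.array([1.2, 0.5]))  # bypass construction guard
        with pytest.raises(ValidationError):
            cre_from_survivor(bad)


class TestAnalyticAndEmpirical:
    @pytest.mark.parametrize(
        "lam, base, expected",
        [(0.5, NATS, 2.0), (1.0, NATS, 1.0), (1.0, BITS, 1 / math.log(2))],
    )
    def test_exponential_analytic(self, lam, base, expected):
        assert cre_exponential_analytic(lam, base).value == pytest.approx(expected, rel=1e-12)

    def test_analytic_rejects_bad_rate(self):
        with pytest.raises(ParameterError):
            cre_exponential_analytic(-1.0)

    def test_hand_computed_step_plugin(self):
        res = cre_empirical(RTSample([1.0, 2.0, 3.0]), method="step")
        assert res.value == pytest.approx(CRE_123, abs=1e-12)
        assert res.method == "empirical_step"

    def test_constant_sample_has_zero_entropy(self):
        assert cre_empirical(RTSample([7.0, 7.0, 7.0])).value == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(EstimatorError):
            cre_empirical(RTSample([5.0]))

    def test_plugin_converges_to_analytic(self):
        # Exp(1): CRE = 1; plug-in at n = 10^5 within 3% (mean over 10 seeds)
        vals = [cre_empirical(Exponential(1.0).rvs(100_000, seed=s)).value
                for s in range(10)]
        assert np.mean(vals) == pytest.approx(1.0, rel=0.03)


class TestCREDensity:
    def test_limits_and_maximum(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        surv = FunctionCurve(t, np.array([1.0, 0.5, 1 / math.e, 0.0]), "survivor")
        dens = cre_density(surv, NATS)
        assert dens.values[0] == 0.0                      # S = 1
        assert dens.values[3] == 0.0                      # S = 0 (x log x -> 0)
        assert dens.values[2] == pytest.approx(1 / math.e, rel=1e-12)
        assert np.all(dens.values <= 1 / math.e + 1e-12)  # global max of -S ln S

    def test_integral_recovers_cre(self, exg_baseline, grid_ms):
        surv = exg_baseline.survivor(grid_ms)
        dens = cre_density(surv)
        total = np.trapezoid(dens.values, dens.t)
        assert total == pytest.approx(cre_from_survivor(surv).value, rel=1e-9)


class TestICRE:
    def test_pointwise_values(self):
        surv = FunctionCurve(np.array([0.0, 1.0]), np.array([1.0, 0.5]), "survivor")
        curve = icre(surv, BITS)
        assert curve.values[0] == 0.0       # S = 1: no information yet
        assert curve.values[1] == pytest.approx(1.0)  # S = 1/2 is one bit

    def test_s_zero_points_are_excluded(self):
        surv = FunctionCurve(np.array([0.0, 1.0, 2.0]),
                             np.array([1.0, 0.5, 0.0]), "survivor")
        curve = icre(surv)
        assert curve.excluded_tail == 1
        assert len(curve) == 2

    def test_identity_with_cumulative_hazard(self, exg_baseline, grid_ms):
        surv = exg_baseline.survivor(grid_ms)
        ic = icre(surv, NATS)
        H = cumulative_hazard(surv, NATS)
        assert np.array_equal(ic.t, H.t)
        assert np.array_equal(ic.values, H.values)

    def test_empirical_curve_is_nondecreasing(self, exg_baseline):
        curve = icre_from_sample(exg_baseline.rvs(500, seed=2))
        assert np.all(np.diff(curve.values) >= 0)
        assert curve.excluded_tail == 1  # the largest observation


class TestSlope:
    @pytest.mark.parametrize("lam", [0.25, 1.0, 3.0])
    @pytest.mark.parametrize("qlo", [0.0, 0.9])
    def test_recovers_exponential_rate_exactly(self, lam, qlo):
        t = np.linspace(0.0, 10.0 / lam, 500)
        curve = icre(Exponential(lam).survivor(t))
        fit = icre_slope(curve, fit_lower_quantile=qlo)
        assert fit.slope == pytest.approx(lam, rel=1e-12, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_window_and_metadata(self, exg_baseline):
        sample = exg_baseline.rvs(1000, seed=4)
        curve = icre_from_sample(sample)
        fit = icre_slope(curve, fit_lower_quantile=0.9)
        assert fit.n_points == 100
        assert fit.fit_window[0] >= np.quantile(sample.durations, 0.85)
        assert fit.stderr > 0

    def test_trim_upper_quantile_shrinks_window(self, exg_baseline):
        curve = icre_from_sample(exg_baseline.rvs(1000, seed=4))
        full = icre_slope(curve, fit_lower_quantile=0.0)
        trimmed = icre_slope(curve, fit_lower_quantile=0.0, trim_upper_quantile=0.2)
        assert trimmed.n_points < full.n_points
        assert trimmed.fit_window[1] < full.fit_window[1]

    def test_too_few_points_rejected(self):
        curve = icre(FunctionCurve(np.array([0.0, 1.0]),
                                   np.array([1.0, 0.5]), "survivor"))
        with pytest.raises(EstimatorError):
            icre_slope(curve, fit_lower_quantile=0.0)


class TestInvariances:
    def test_shift_invariance(self, grid_ms):
        # CRE(X + c) = CRE(X): the mu = 400 and mu = 800 models agree
        from rtentropy import ExGaussian

        a = cre_from_survivor(ExGaussian(400, 30, 60).survivor(grid_ms)).value
        b = cre_from_survivor(ExGaussian(800, 30, 60).survivor(grid_ms)).value
        assert abs(a - b) / a < 0.005

    @pytest.mark.parametrize("a", [0.5, 2.0, 10.0])
    def test_scale_equivariance_exponential(self, a):
        # aX ~ Exp(lam/a), so CRE scales by a exactly
        lam = 0.8
        base_val = cre_exponential_analytic(lam).value
        scaled = cre_exponential_analytic(lam / a).value
        assert scaled == pytest.approx(a * base_val, rel=1e-12)


class TestHazardInBits:
    def test_scaling(self):
        t = np.arange(0.0, 3.0)
        h = FunctionCurve(t, np.array([math.log(2.0), 1.0, 0.0]), "hazard")
        b = hazard_in_bits(h)
        assert b.values[0] == pytest.approx(1.0, rel=1e-12)
        assert b.values[1] == pytest.approx(1 / math.log(2), rel=1e-12)
        assert b.values[2] == 0.0

    def test_requires_hazard_curve(self):
        surv = FunctionCurve(np.array([0.0, 1.0]), np.array([1.0, 0.5]), "survivor")
        with pytest.raises(UsageError):
            hazard_in_bits(surv)
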