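import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbshape import SimConfig, TbTrace, simulate_trace
from tbshape.errors import EvaluationRangeError, FitError, ValidationError
from tbshape.quantile_smoothing import (
    evaluate_curve,
    fit_quantile_curve,
    fit_quantile_spline,
    penalized_objective,
    pinball_loss,
    rearrange_noncrossing,
    select_lambda,
)

from .oracles import brute_force_min_objective, scalar_quantile_minimizer


class TestPinballLoss:
    def test_formula_positive_residual(self):
        assert pinball_loss(1.0, 0.55) == pytest.approx(0.55)

    def test_formula_negative_residual(self):
        assert pinball_loss(-1.0, 0.55) == pytest.approx(0.45)

    def test_zero_residual(self):
        for tau in (0.1, 0.45, 0.9):
            assert pinball_loss(0.0, tau) == 0.0

    def test_invalid_tau(self):
        with pytest.raises(ValidationError):
            pinball_loss(1.0, 0.0)
        with pytest.raises(ValidationError):
            pinball_loss(1.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        # subnormal u underflows u*tau to zero; the property is about reals
        u=st.floats(-100, 100).filter(lambda v: v == 0 or abs(v) > 1e-300),
        tau=st.floats(0.01, 0.99),
    )
    def test_nonnegative_zero_iff_zero(self, u, tau):
        loss = pinball_loss(u, tau)
        assert loss >= 0
        assert (loss == 0) == (u == 0)


def _flat_trace(value=37.0, hours=120.0):
    t = np.arange(0, hours, 0.5)
    return TbTrace(time_h=t, tb_c=np.full(t.size, value))


class TestFitQuantileCurve:
    def test_constant_trace_zero_objective(self):
        curve = fit_quantile_curve(_flat_trace(), 0.55)
        assert curve.objective == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            curve(np.array([0.0, 50.0, 119.5])), 37.0, atol=1e-8
        )

    def test_short_segment_refused(self):
        t = np.arange(0, 48, 0.5)
        tr = TbTrace(time_h=t, tb_c=np.full(t.size, 37.0))
        with pytest.raises(FitError, match="short"):
            fit_quantile_curve(tr, 0.55)

    def test_knot_spacing_floor(self):
        with pytest.raises(ValidationError, match="floor"):
            fit_quantile_curve(_flat_trace(), 0.55, knot_spacing_h=24.0)

    def test_degenerate_design_refused(self):
        with pytest.raises(FitError, match="degenerate"):
            fit_quantile_spline([0.0, 1.0], [36.0, 37.0], 0.5, [], degree=3)

    def test_objective_invariant_recomputes(self, default_trace):
        curve = fit_quantile_curve(default_trace, 0.55)
        recomputed = penalized_objective(
            default_trace.time_h, default_trace.tb_c, curve
        )
        assert curve.objective == pytest.approx(recomputed, abs=1e-8)

    def test_clustered_points_lambda_inf_hits_scalar_quantile(self):
        # 10 readings at one design location, 4 x 36 and 6 x 38, tau=0.55:
        # the scalar check-loss minimizer (grid search) is 38.0
        y = np.array([36.0] * 4 + [38.0] * 6)
        assert scalar_quantile_minimizer(y, 0.55) == pytest.approx(38.0, abs=1e-3)
        t = np.full(10, 5.0)
        curve = fit_quantile_spline(t, y, 0.55, [], degree=3, lam=1e6,
                                    span=(0.0, 10.0))
        assert curve(5.0)[0] == pytest.approx(38.0, abs=1e-6)

    def test_coverage_at_tau_55(self, default_trace):
        curve = fit_quantile_curve(default_trace, 0.55)
        frac = np.mean(default_trace.tb_c < curve(default_trace.time_h))
        assert 0.52 <= frac <= 0.58

    def test_lambda_inf_flattens_to_empirical_quantile(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 500, 0.1)
        tr = TbTrace(time_h=t, tb_c=rng.normal(37, 0.5, t.size))
        curve = fit_quantile_curve(tr, 0.55, lam=1e6)
        emp = np.quantile(tr.tb_c, 0.55)
        assert np.abs(curve(tr.time_h) - emp).max() < 0.05

    def test_tracks_slow_drift_not_daily_cycle(self):
        cfg = SimConfig(drift_c_per_day=0.15, seed=3)
        tr = simulate_trace(cfg)
        curve = fit_quantile_curve(tr, 0.55)
        vals = curve(tr.time_h)
        rise = vals[-1] - vals[0]
        assert 3.0 < rise < 6.0  # ~4.5 degC of drift over 30 d
        # and no daily wiggle of the +/-1 degC circadian amplitude
        one_day = vals[:144]
        assert one_day.max() - one_day.min() < 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5])
    def test_brute_force_oracle_equivalence_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        t = np.sort(rng.uniform(0, 10, n))
        y = rng.normal(37, 1, n)
        tau = float(rng.uniform(0.2, 0.8))
        lam = float(rng.choice([0.0, 0.3, 2.0]))
        degree = int(rng.integers(1, 3))  # 2 or 3 coefficients
        curve = fit_quantile_spline(t, y, tau, [], degree=degree, lam=lam,
                                    span=(0.0, 10.0))
        from scipy.interpolate import BSpline

        B = BSpline.design_matrix(
            t, curve.full_knots, degree, extrapolate=False
        ).toarray()
        oracle = brute_force_min_objective(B, y, tau, lam)
        assert curve.objective == pytest.approx(oracle, abs=1e-3)


class TestEvaluateCurve:
    def test_outside_span_refused(self):
        curve = fit_quantile_curve(_flat_trace(), 0.5)
        with pytest.raises(EvaluationRangeError):
            evaluate_curve(curve, [-1.0])
        with pytest.raises(EvaluationRangeError):
            evaluate_curve(curve, [200.0])

    def test_continuous_at_knots(self, default_trace):
        curve = fit_quantile_curve(default_trace, 0.55)
        for knot in curve.knots_h:
            left = evaluate_curve(curve, [knot - 1e-9])[0]
            right = evaluate_curve(curve, [knot + 1e-9])[0]
            at = evaluate_curve(curve, [knot])[0]
            assert at == pytest.approx(left, abs=1e-6)
            assert at == pytest.approx(right, abs=1e-6)

    def test_span_endpoints_evaluable(self):
        curve = fit_quantile_curve(_flat_trace(), 0.5)
        t0, t1 = curve.span_h
        vals = evaluate_curve(curve, [t0, t1])
        np.testing.assert_allclose(vals, 37.0, atol=1e-8)


class TestRearrangeNoncrossing:
    def test_noncrossing_inputs_unchanged(self, default_trace):
        lo = fit_quantile_curve(default_trace, 0.45)
        hi = fit_quantile_curve(default_trace, 0.55)
        t = default_trace.time_h
        out_lo, out_hi = rearrange_noncrossing(lo, hi, t)
        assert np.all(out_lo <= out_hi)
        raw_lo, raw_hi = lo(t), hi(t)
        ok = raw_lo <= raw_hi
        np.testing.assert_array_equal(out_lo[ok], raw_lo[ok])
        np.testing.assert_array_equal(out_hi[ok], raw_hi[ok])

    def test_identical_curves_identity(self, default_trace):
        c = fit_quantile_curve(default_trace, 0.45)
        from dataclasses import replace

        c_hi = replace(c, tau=0.55)
        t = default_trace.time_h[:100]
        lo, hi = rearrange_noncrossing(c, c_hi, t)
        np.testing.assert_array_equal(lo, hi)

    def test_tau_order_enforced(self, default_trace):
        lo = fit_quantile_curve(default_trace, 0.45)
        hi = fit_quantile_curve(default_trace, 0.55)
        with pytest.raises(ValidationError):
            rearrange_noncrossing(hi, lo, default_trace.time_h)

    def test_monotone_in_tau_everywhere(self, default_trace):
        lo = fit_quantile_curve(default_trace, 0.45)
        hi = fit_quantile_curve(default_trace, 0.55)
        grid = np.linspace(*lo.span_h, 2000)
        out_lo, out_hi = rearrange_noncrossing(lo, hi, grid)
        assert np.all(out_lo <= out_hi)


class TestSelectLambda:
    def test_returns_candidate(self):
        tr = simulate_trace(SimConfig(duration_days=7.0, seed=2))
        lam = select_lambda(tr, 0.55, lambdas=(0.1, 10.0), n_folds=3)
        assert lam in (0.1, 10.0)
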