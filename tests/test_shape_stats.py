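import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbshape import (
    StatsConfig,
    classify_skew,
    dip_statistic,
    dip_test,
    empirical_quantile,
    kde_mode,
    shape_report,
    skewness,
)
from tbshape.errors import InsufficientDataError, ValidationError

from .oracles import dip_brute_force


class TestKdeMode:
    def test_degenerate_all_equal(self):
        assert kde_mode([37.0, 37.0, 37.0]) == 37.0
        assert kde_mode([36.2]) == 36.2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            kde_mode([])

    def test_normal_mode_near_mean(self, rng):
        x = rng.normal(37.0, 0.5, 5000)
        assert kde_mode(x) == pytest.approx(37.0, abs=0.15)

    def test_mixture_mode_at_heavier_component(self, rng):
        x = np.concatenate([
            rng.normal(38.0, 0.3, 3500),
            rng.normal(35.0, 0.3, 1500),
        ])
        assert kde_mode(x) == pytest.approx(38.0, abs=0.15)

    def test_bias_decreases_with_n(self):
        errs = []
        for n in (500, 5000):
            devs = [
                abs(kde_mode(np.random.default_rng(s).normal(37, 0.5, n)) - 37.0)
                for s in range(8)
            ]
            errs.append(np.mean(devs))
        assert errs[1] < errs[0]

    def test_order_invariance(self, rng):
        x = rng.normal(36, 1, 300)
        assert kde_mode(x) == kde_mode(x[::-1])


class TestEmpiricalQuantile:
    def test_median_of_odd_set(self):
        assert empirical_quantile([1, 2, 3, 4, 5], 0.5) == 3.0

    def test_linear_interpolation_convention(self):
        # {0, 10} at p=0.10: (n-1)p = 0.1 -> 0 + 0.1 * 10 = 1.0
        assert empirical_quantile([0.0, 10.0], 0.10) == pytest.approx(1.0)

    def test_monotone_in_p(self, rng):
        x = rng.uniform(30, 40, 100)
        assert empirical_quantile(x, 0.10) <= empirical_quantile(x, 0.90)

    def test_invalid_level(self):
        with pytest.raises(ValidationError):
            empirical_quantile([1.0], 0.0)


class TestSkewness:
    def test_symmetric_sample_zero(self):
        assert skewness([-1.0, 0.0, 1.0], "moment") == pytest.approx(0.0)
        assert skewness([-1.0, 0.0, 1.0], "quantile") == pytest.approx(0.0)

    def test_antisymmetry(self, rng):
        x = rng.exponential(1.0, 200) + 30
        for method in ("moment", "quantile"):
            assert skewness(-x, method) == pytest.approx(
                -skewness(x, method), abs=1e-10
            )

    def test_exponential_moment_skew_near_two(self, rng):
        x = rng.exponential(1.0, 50000)
        assert skewness(x, "moment") == pytest.approx(2.0, abs=0.15)

    def test_location_scale_invariance(self, rng):
        x = rng.exponential(1.0, 500)
        for method in ("moment", "quantile"):
            assert skewness(3.0 * x + 7.0, method) == pytest.approx(
                skewness(x, method), abs=1e-9
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            skewness([5.0, 5.0, 5.0])


class TestClassifySkew:
    def test_symmetric_normal(self, rng):
        x = rng.normal(37, 0.5, 3000)
        assert classify_skew(x, seed=0) == "symmetric"

    def test_torpor_overall_left(self, torpor_trace):
        assert classify_skew(torpor_trace.tb_c, seed=0) == "left"

    def test_burst_active_right(self, burst_trace):
        active = burst_trace.tb_c[burst_trace.truth_labels == "ACTIVE"]
        assert classify_skew(active, seed=0) == "right"

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, 100)
        assert classify_skew(x, seed=42) == classify_skew(x, seed=42)

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify_skew(np.arange(10.0))


class TestDipStatistic:
    def test_equally_spaced_is_half_over_n(self):
        for n in (4, 7, 10, 50):
            assert dip_statistic(np.arange(1.0, n + 1)) == pytest.approx(
                1.0 / (2 * n), abs=1e-12
            )

    def test_bounds(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 200))
            x = rng.normal(0, 1, n)
            d = dip_statistic(x)
            assert 1.0 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, seed, a, b):
        x = np.random.default_rng(seed).normal(0, 1, 40)
        assert dip_statistic(a * x + b) == pytest.approx(
            dip_statistic(x), abs=1e-9
        )

    def test_mixture_dips_higher_than_normal(self, rng):
        z = rng.normal(0, 1, 2000)
        mixture = np.concatenate([z[:1000], z[1000:] + 6.0])
        assert dip_statistic(mixture) > dip_statistic(z)

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            dip_statistic([1.0, 2.0, 3.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_equivalence(self, seed):
        # continuous draws only: the piecewise-linear LP oracle does not
        # model atoms; tie handling is pinned separately below
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        kind = seed % 3
        if kind == 0:
            x = rng.normal(0, 1, n)
        elif kind == 1:
            x = np.concatenate(
                [rng.normal(0, 1, n // 2), rng.normal(6, 1, n - n // 2)]
            )
        else:
            x = rng.lognormal(0, 0.8, n)
        assert dip_statistic(x) == pytest.approx(dip_brute_force(x), abs=1e-9)

    @pytest.mark.parametrize(
        "values, expected",
        [
            # reference values from the published reference implementation
            # (R package diptest 0.77 / its C port, diptest 0.10.0)
            ([1.0, 1.0, 2.0, 2.0, 3.0, 3.0], 1.0 / 6.0),
            ([5.0] * 10 + [6.0, 7.0, 8.0], 0.038461538461538464),
            ([0.0] * 20 + [1.0] * 20, 0.25),
        ],
    )
    def test_tied_samples_match_reference(self, values, expected):
        assert dip_statistic(values) == pytest.approx(expected, abs=1e-12)


class TestDipTest:
    def test_separated_mixture_significant(self, rng):
        x = np.concatenate([
            rng.normal(35.0, 0.3, 1000),
            rng.normal(38.0, 0.3, 1000),
        ])
        _, p = dip_test(x, n_mc=199, seed=0)
        assert p < 0.05

    def test_normal_usually_not_significant(self):
        not_rejected = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(37, 0.5, 2000)
            _, p = dip_test(x, n_mc=199, seed=seed)
            not_rejected += p >= 0.05
        assert not_rejected >= 9

    def test_p_value_bounds(self, rng):
        x = rng.normal(0, 1, 50)
        _, p = dip_test(x, n_mc=199, seed=1)
        assert 1.0 / 200 <= p <= 1.0

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, 100)
        assert dip_test(x, n_mc=199, seed=3) == dip_test(x, n_mc=199, seed=3)


class TestShapeReport:
    def test_bimodal_plateau_trace(self, default_trace):
        rep = shape_report(default_trace.tb_c, StatsConfig(n_mc=199))
        assert rep.bimodal is True
        assert rep.dip_p < 0.05

    def test_rest_phase_unimodal(self, default_trace):
        rest = default_trace.tb_c[default_trace.truth_labels == "REST"]
        rep = shape_report(rest, StatsConfig(n_mc=199))
        assert rep.bimodal is False

    def test_partial_report_small_sample(self):
        rep = shape_report(np.linspace(35, 38, 10))
        assert np.isfinite(rep.mode_c)
        assert np.isfinite(rep.q10_c) and np.isfinite(rep.q90_c)
        assert rep.dip_stat is None and rep.dip_p is None
        assert rep.skew_class is None and rep.bimodal is None

    def test_fields_mutually_consistent(self, rng):
        x = rng.normal(37, 1, 500)
        rep = shape_report(x, StatsConfig(n_mc=199))
        assert rep.bimodal == (rep.dip_p < 0.05)
        assert rep.q10_c <= rep.q90_c
        assert rep.n == 500

    def test_order_invariance(self, rng):
        x = rng.normal(37, 1, 200)
        cfg = StatsConfig(n_mc=199)
        a = shape_report(x, cfg)
        b = shape_report(np.sort(x)[::-1], cfg)
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            shape_report([])
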