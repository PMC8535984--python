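import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from greycast import (
    GaussianSpec,
    LogTransform,
    RawSeries,
    ShiftTransform,
    accumulate,
    assemble_system,
    background_values,
    error_report,
    estimate_parameters,
    fit_grey_model,
    forecast,
    order_ratio_check,
    predict_cumulative,
    restore_increments,
)
from greycast.exceptions import (
    DegenerateModelError,
    InadmissibleSeriesError,
    InternalConsistencyError,
    InvalidSpecError,
    OrderRatioWarning,
    SingularSystemError,
    ZeroDenominatorError,
)
from greycast.grey_core import DesignSystem

positive_series = st.lists(
    st.floats(min_value=0.1, max_value=1e6, allow_nan=False, allow_infinity=False),
    min_size=4,
    max_size=30,
)


def exact_discrete_series(a, b, first, n, spec=None):
    """Series satisfying the grey difference equation with zero residuals."""
    mu, s2 = (spec.mu, spec.sigma**2) if spec else (None, None)
    values = [first]
    x1_prev = first
    for k in range(2, n + 1):
        if spec is None:
            xk = (b - a * x1_prev) / (1 + a / 2)
        else:
            xk = ((k - 0.5 - mu) / s2 * (b - a * x1_prev)) / (
                1 + a * (k - mu) / (2 * s2)
            )
        values.append(xk)
        x1_prev += xk
    values = np.array(values)
    assert np.all(values > 0), "test helper produced a non-positive series"
    return RawSeries.from_values(values)


class TestOrderRatio:
    def test_constant_series_is_admissible(self):
        report = order_ratio_check(RawSeries.from_values([5.0] * 4))
        np.testing.assert_array_equal(report.ratios, np.ones(3))
        assert report.admissible
        assert report.lower_bound == pytest.approx(math.exp(-2 / 5))
        assert report.upper_bound == pytest.approx(math.exp(2 / 5))

    def test_fixture_first_ratio(self, accident_series):
        with pytest.warns(OrderRatioWarning):
            report = order_ratio_check(accident_series)
        assert report.ratios[0] == pytest.approx(120351 / 130491)
        assert report.ratios[0] == pytest.approx(0.92229, abs=1e-5)

    def test_fixture_2016_drop_is_flagged_but_advisory(self, accident_series):
        with pytest.warns(OrderRatioWarning):
            report = order_ratio_check(accident_series)
        assert not report.admissible
        assert 2016 in report.violating_years
        k_2016 = 17  # 2016 is the 17th observation
        assert report.ratios[k_2016 - 2] == pytest.approx(66182 / 43062)
        assert report.ratios[k_2016 - 2] > report.upper_bound

    def test_strict_mode_raises(self, accident_series):
        with pytest.raises(InadmissibleSeriesError):
            order_ratio_check(accident_series, strict=True)


class TestTransforms:
    def test_accumulate_small_example(self):
        np.testing.assert_array_equal(accumulate([1, 2, 3]), [1, 3, 6])

    def test_accumulate_fixture_prefix(self, accident_series):
        assert accumulate(accident_series)[1] == 120351 + 130491

    @settings(derandomize=True, max_examples=50)
    @given(positive_series)
    def test_restore_accumulate_roundtrip(self, values):
        values = np.asarray(values)
        np.testing.assert_allclose(
            restore_increments(accumulate(values)), values, rtol=1e-12, atol=1e-9
        )

    def test_restore_small_example(self):
        np.testing.assert_array_equal(restore_increments([1, 3, 6]), [1, 2, 3])
        np.testing.assert_array_equal(restore_increments([7.0]), [7.0])


class TestBackgroundValues:
    def test_classical_is_adjacent_mean(self):
        np.testing.assert_array_equal(background_values(np.array([1.0, 3.0])), [2.0])

    def test_gaussian_standard_weights(self):
        # z(2) = (2*x1(2) + 1*x1(1)) / 2 with mu=0, sigma=1
        z = background_values(np.array([1.0, 3.0]), GaussianSpec())
        np.testing.assert_array_equal(z, [3.5])

    def test_gaussian_general_spec_matches_direct_formula(self):
        x1 = np.array([2.0, 5.0, 9.0, 10.0])
        spec = GaussianSpec(mu=1.5, sigma=2.0)
        z = background_values(x1, spec)
        k = np.arange(2, 5)
        expected = 0.5 * (
            (k - 1.5) / 4.0 * x1[1:] + (k - 2.5) / 4.0 * x1[:-1]
        )
        np.testing.assert_allclose(z, expected, rtol=1e-15)

    def test_classical_lies_between_adjacent_levels(self):
        x1 = accumulate([3.0, 1.0, 4.0, 1.5, 5.0])
        z = background_values(x1)
        assert np.all(z >= x1[:-1]) and np.all(z <= x1[1:])


class TestAssembleSystem:
    def test_classical_second_column_is_ones(self):
        x0 = np.array([1.0, 2.0, 3.0])
        sys = assemble_system(x0, background_values(accumulate(x0)))
        assert sys.B.shape == (2, 2)
        np.testing.assert_array_equal(sys.B[:, 1], [1.0, 1.0])

    def test_gaussian_second_column_is_shifted_midpoints(self):
        x0 = np.array([1.0, 2.0, 3.0])
        spec = GaussianSpec()
        sys = assemble_system(x0, background_values(accumulate(x0), spec), spec)
        np.testing.assert_array_equal(sys.B[:, 1], [1.5, 2.5])

    def test_y_stacks_fixture_tail(self, accident_series):
        cum = accumulate(accident_series)
        sys = assemble_system(accident_series, background_values(cum))
        assert len(sys.Y) == 20
        np.testing.assert_array_equal(sys.Y[:2], [130491, 139393])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InternalConsistencyError):
            assemble_system(np.array([1.0, 2.0, 3.0]), np.array([1.0]))


class TestEstimateParameters:
    @pytest.mark.parametrize("spec", [None, GaussianSpec(), GaussianSpec(mu=0.5, sigma=1.5)])
    def test_zero_residual_recovery(self, spec):
        a, b = 0.02, 400.0
        series = exact_discrete_series(a, b, first=100.0, n=8, spec=spec)
        cum = accumulate(series)
        sys = assemble_system(series, background_values(cum, spec), spec)
        a_hat, b_hat = estimate_parameters(sys)
        assert a_hat == pytest.approx(a, rel=1e-10)
        assert b_hat == pytest.approx(b, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_least_squares_optimality_under_perturbation(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(10, 100, size=8)
        series = RawSeries.from_values(values)
        sys = assemble_system(series, background_values(accumulate(series)))
        a, b = estimate_parameters(sys)
        rss = np.sum((sys.Y - sys.B @ [a, b]) ** 2)
        for da in (-1e-3, 0, 1e-3):
            for db in (-1e-3, 0, 1e-3):
                if da == db == 0:
                    continue
                perturbed = np.sum((sys.Y - sys.B @ [a + da, b + db]) ** 2)
                assert perturbed >= rss

    def test_scaling_y_scales_b_only(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(10, 100, size=6)
        series = RawSeries.from_values(values)
        sys = assemble_system(series, background_values(accumulate(series)))
        a1, b1 = estimate_parameters(sys)
        scaled = RawSeries.from_values(values * 3.5)
        sys2 = assemble_system(scaled, background_values(accumulate(scaled)))
        a2, b2 = estimate_parameters(sys2)
        assert a2 == pytest.approx(a1, rel=1e-10)
        assert b2 == pytest.approx(3.5 * b1, rel=1e-10)

    def test_rank_deficient_system_rejected(self):
        sys = DesignSystem(B=np.array([[-2.0, 1.0], [-2.0, 1.0]]), Y=np.array([1.0, 2.0]))
        with pytest.raises(SingularSystemError):
            estimate_parameters(sys)


class TestPredictCumulative:
    def test_anchoring_at_k1_both_modes(self):
        for spec in (None, GaussianSpec(), GaussianSpec(mu=-1.0, sigma=2.0)):
            cum = predict_cumulative(120.0, a=0.05, b=10.0, spec=spec, k_max=5)
            assert cum[0] == pytest.approx(120.0, rel=1e-12)

    def test_unanchored_variant_matches_as_printed_form(self):
        spec = GaussianSpec()
        a, b, first = 0.05, 10.0, 120.0
        cum = predict_cumulative(first, a, b, spec=spec, k_max=4, anchored=False)
        k = np.arange(1, 5)
        expected = (first - b / a) * np.exp(-a / 2) * np.exp(-a * k**2 / 2) + b / a
        np.testing.assert_allclose(cum, expected, rtol=1e-14)
        assert cum[0] != pytest.approx(first, rel=1e-6)

    def test_classical_saturates_monotonically(self):
        cum = predict_cumulative(10.0, a=0.3, b=30.0, k_max=60)
        level = 30.0 / 0.3
        assert np.all(np.diff(cum) > 0)
        assert cum[-1] == pytest.approx(level, rel=1e-6)

    def test_gaussian_increments_single_peaked(self):
        # saturating S-curve: increments rise then fall
        cum = predict_cumulative(
            100.0, a=0.05, b=0.05 * 2000.0, spec=GaussianSpec(), k_max=21
        )
        inc = restore_increments(cum)[1:]
        assert np.all(inc > 0)
        peak = int(np.argmax(inc))
        assert 0 < peak < len(inc) - 1
        assert np.all(np.diff(inc[: peak + 1]) > 0)
        assert np.all(np.diff(inc[peak:]) < 0)

    def test_zero_development_coefficient_rejected(self):
        with pytest.raises(DegenerateModelError):
            predict_cumulative(1.0, a=0.0, b=1.0, k_max=3)

    def test_bad_k_max_rejected(self):
        with pytest.raises(InvalidSpecError):
            predict_cumulative(1.0, a=0.1, b=1.0, k_max=0)


class TestErrorReport:
    def test_perfect_fit_is_all_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        rep = error_report(obs, obs.copy())
        np.testing.assert_array_equal(rep.signed, np.zeros(3))
        assert rep.delta == 0 and rep.max_abs == 0

    def test_fitted_denominator_reproduces_published_cells(self):
        gm_2001 = error_report(
            np.array([130491.0]), np.array([153846.738]), denominator="fitted"
        )
        assert round(gm_2001.max_abs, 6) == 0.151812
        ggm_2015 = error_report(
            np.array([66182.0]), np.array([63816.640]), denominator="fitted"
        )
        assert round(ggm_2015.max_abs, 6) == 0.037065

    def test_observed_denominator_convention(self):
        rep = error_report(np.array([100.0, 200.0]), np.array([110.0, 190.0]))
        np.testing.assert_allclose(rep.signed, [0.1, -0.05])
        assert rep.delta == pytest.approx(0.075)
        assert rep.max_abs >= rep.delta

    def test_zero_denominator_names_year(self):
        with pytest.raises(ZeroDenominatorError, match="2001"):
            error_report(
                np.array([1.0, 0.0]),
                np.array([1.0, 1.0]),
                years=np.array([2000, 2001]),
            )


@pytest.mark.filterwarnings("ignore::greycast.exceptions.OrderRatioWarning")
class TestFitGreyModel:
    def test_deterministic_bit_identical(self, accident_series):
        fit1 = fit_grey_model(accident_series, mode="ggm")
        fit2 = fit_grey_model(accident_series, mode="ggm")
        assert fit1.a == fit2.a and fit1.b == fit2.b
        np.testing.assert_array_equal(fit1.fitted_values, fit2.fitted_values)

    def test_classical_fitted_increments_have_constant_ratio(self, accident_series):
        fit = fit_grey_model(accident_series, mode="gm")
        ratios = fit.fitted_values[2:] / fit.fitted_values[1:-1]
        np.testing.assert_allclose(ratios, math.exp(-fit.a), rtol=1e-12)

    def test_classical_scale_equivariance(self, accident_series):
        fit = fit_grey_model(accident_series, mode="gm")
        scaled = accident_series.with_values(accident_series.values * 2.5)
        fit2 = fit_grey_model(scaled, mode="gm")
        assert fit2.a == pytest.approx(fit.a, rel=1e-10)
        assert fit2.b == pytest.approx(2.5 * fit.b, rel=1e-10)
        np.testing.assert_allclose(
            fit2.fitted_values, 2.5 * fit.fitted_values, rtol=1e-10
        )
        np.testing.assert_allclose(fit2.errors.signed, fit.errors.signed, rtol=1e-8)

    def test_ggm_anchors_first_fitted_value(self, accident_series):
        fit = fit_grey_model(accident_series, mode="ggm")
        assert fit.fitted_values[0] == pytest.approx(
            accident_series.values[0], rel=1e-12
        )
        assert fit.gaussian == GaussianSpec(mu=0.0, sigma=1.0)

    def test_error_metric_consistency(self, accident_series):
        fit = fit_grey_model(accident_series, mode="gm", error_denominator="fitted")
        abs_err = np.abs(fit.errors.signed)
        assert fit.errors.delta == pytest.approx(abs_err.mean())
        assert fit.errors.max_abs == pytest.approx(abs_err.max())
        assert fit.errors.max_abs >= fit.errors.delta

    def test_shift_transform_inverts_on_predictions(self, accident_series):
        fit = fit_grey_model(
            accident_series, mode="gm", transform=ShiftTransform(50000.0)
        )
        # errors are computed on the original scale
        assert np.all(np.isfinite(fit.errors.signed))
        assert fit.fitted_values[0] == pytest.approx(
            accident_series.values[0], rel=1e-12
        )

    def test_log_transform_keeps_predictions_positive(self, accident_series):
        fit = fit_grey_model(accident_series, mode="gm", transform=LogTransform())
        assert np.all(fit.fitted_values > 0)
        fc = forecast(fit, 5)
        assert np.all(fc.values > 0)


@pytest.mark.filterwarnings("ignore::greycast.exceptions.OrderRatioWarning")
class TestForecast:
    def test_horizon_must_be_positive(self, accident_series):
        fit = fit_grey_model(accident_series, mode="gm")
        with pytest.raises(InvalidSpecError):
            forecast(fit, 0)

    def test_classical_forecast_decays_geometrically(self, accident_series):
        fit = fit_grey_model(accident_series, mode="gm")
        fc = forecast(fit, 6)
        ratios = fc.values[1:] / fc.values[:-1]
        np.testing.assert_allclose(ratios, math.exp(-fit.a), rtol=1e-12)
        np.testing.assert_array_equal(fc.years, np.arange(2021, 2027))

    def test_ggm_ten_year_forecast_positive_and_decreasing(self, accident_series):
        fit = fit_grey_model(accident_series, mode="ggm")
        fc = forecast(fit, 10)
        assert np.all(fc.values > 0)
        assert np.all(np.diff(fc.values) < 0)

    def test_forecast_continues_fitted_cumulative(self, accident_series):
        fit = fit_grey_model(accident_series, mode="ggm")
        fc = forecast(fit, 3)
        n = accident_series.n
        from greycast import predict_cumulative as pc

        cum = pc(
            accident_series.values[0],
            fit.a,
            fit.b,
            spec=fit.gaussian,
            k_max=n + 3,
        )
        np.testing.assert_allclose(fc.values, np.diff(cum)[n - 1 :], rtol=1e-12)
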