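import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st
from scipy import stats

from dicentric import (
    AberrationDistribution,
    CalibrationCurve,
    CapabilityError,
    CIMethod,
    DEFAULT_CONVERSION_TABLE,
    DoseConversionTable,
    InputError,
    convert_dose,
    curve_yield,
    estimate_dose,
    invert_dose,
    poisson_yield_ci,
    simulate_distribution,
)
from dicentric.dose import MERKLE_COMPONENT_LEVEL


class TestGarwoodLimits:
    def test_zero_count_lower_limit_is_zero(self):
        lo, hi = poisson_yield_ci(0, 100)
        assert lo == 0.0 and hi > 0.0

    def test_chi_square_relation(self):
        # independent evaluation of the chi-square construction
        lo, hi = poisson_yield_ci(10, 100, 0.95)
        assert lo == pytest.approx(stats.chi2.ppf(0.025, 20) / 2 / 100, abs=1e-4)
        assert hi == pytest.approx(stats.chi2.ppf(0.975, 22) / 2 / 100, abs=1e-4)
        assert (lo, hi) == pytest.approx((0.04795, 0.18390), abs=1e-4)

    def test_levels_nest(self):
        wide = poisson_yield_ci(10, 100, 0.95)
        narrow = poisson_yield_ci(10, 100, 0.83)
        assert wide[0] <= narrow[0] <= narrow[1] <= wide[1]

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            poisson_yield_ci(5, 0)
        with pytest.raises(InputError):
            poisson_yield_ci(-1, 100)


class TestInvertDose:
    def test_perfect_square(self):
        curve = CalibrationCurve(background=0.0, alpha=0.0, beta=0.05)
        assert invert_dose(curve, 0.45) == pytest.approx(3.0)

    def test_background_yield_maps_to_zero(self, simple_curve):
        assert invert_dose(simple_curve, simple_curve.background) == 0.0

    def test_round_trip_with_curve_yield(self, simple_curve):
        # y(2.56) = 0.001 + 0.02*2.56 + 0.06*2.56^2 = 0.445416
        assert invert_dose(simple_curve, 0.445416) == pytest.approx(2.56, abs=1e-6)

    def test_flat_curve_has_no_solution(self):
        curve = CalibrationCurve(background=0.001, alpha=0.0, beta=0.0)
        with pytest.raises(InputError):
            invert_dose(curve, 0.5)

    def test_linear_curve(self):
        curve = CalibrationCurve(background=0.001, alpha=0.04, beta=0.0)
        assert invert_dose(curve, 0.081) == pytest.approx(2.0)

    @settings(
        derandomize=True,
        max_examples=100,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(st.floats(min_value=0.0, max_value=15.0))
    def test_inversion_round_trip_property(self, simple_curve, dose):
        y = curve_yield(simple_curve, dose)
        assert invert_dose(simple_curve, y) == pytest.approx(dose, abs=1e-9)


class TestEstimateDose:
    def test_monotone_in_dicentric_count(self, fitted_curve):
        doses = []
        for x in (20, 60, 100, 140):
            sample = AberrationDistribution(counts={0: 200 - x, 1: x})
            doses.append(estimate_dose(fitted_curve, sample).dose)
        assert doses == sorted(doses)
        assert all(b > a for a, b in zip(doses, doses[1:]))

    def test_zero_covariance_matches_yield_only_component_level(self):
        curve = CalibrationCurve(
            background=0.001, alpha=0.03, beta=0.05,
            covariance=np.zeros((3, 3)), max_calibration_dose=5.0,
        )
        sample = AberrationDistribution(counts={0: 120, 1: 60, 2: 20})
        merkle = estimate_dose(curve, sample, CIMethod.CURVE_PLUS_YIELD)
        yield_only = estimate_dose(
            curve, sample, CIMethod.YIELD_ONLY, level=MERKLE_COMPONENT_LEVEL
        )
        assert merkle.ci_low == pytest.approx(yield_only.ci_low, abs=1e-5)
        assert merkle.ci_high == pytest.approx(yield_only.ci_high, abs=1e-5)
        assert merkle.dose == yield_only.dose

    def test_curve_error_widens_interval(self, fitted_curve):
        sample = AberrationDistribution(counts={0: 120, 1: 60, 2: 20})
        merkle = estimate_dose(fitted_curve, sample, CIMethod.CURVE_PLUS_YIELD)
        yield_only = estimate_dose(
            fitted_curve, sample, CIMethod.YIELD_ONLY, level=MERKLE_COMPONENT_LEVEL
        )
        assert merkle.ci_high - merkle.ci_low > yield_only.ci_high - yield_only.ci_low

    def test_interval_brackets_point_estimate(self, fitted_curve, rng):
        for dose in (0.5, 2.0, 4.5):
            sample = simulate_distribution((0.001, 0.03, 0.05), dose, 200, 1.0, rng)
            est = estimate_dose(fitted_curve, sample)
            assert 0.0 <= est.ci_low <= est.dose <= est.ci_high

    def test_extrapolation_flagged(self):
        curve = CalibrationCurve(
            background=0.001, alpha=0.03, beta=0.05,
            covariance=np.zeros((3, 3)), max_calibration_dose=3.0,
        )
        hot = AberrationDistribution(counts={0: 50, 1: 80, 2: 50, 3: 20})
        est = estimate_dose(curve, hot)
        assert est.dose > 3.0 and est.extrapolated
        cool = AberrationDistribution(counts={0: 180, 1: 20})
        assert not estimate_dose(curve, cool).extrapolated

    def test_missing_covariance_is_capability_error(self):
        curve = CalibrationCurve(background=0.001, alpha=0.03, beta=0.05)
        sample = AberrationDistribution(counts={0: 150, 1: 50})
        with pytest.raises(CapabilityError):
            estimate_dose(curve, sample, CIMethod.CURVE_PLUS_YIELD)
        est = estimate_dose(curve, sample, CIMethod.YIELD_ONLY)
        assert est.dose > 0

    def test_yield_below_background_gives_zero(self, fitted_curve):
        sample = AberrationDistribution(counts={0: 10**6})
        est = estimate_dose(fitted_curve, sample)
        assert est.dose == 0.0 and est.ci_low == 0.0


class TestDoseConversion:
    @pytest.mark.parametrize(
        "kerma,blood", [(2.56, 2.71), (3.41, 3.60), (4.54, 4.80)]
    )
    def test_packaged_anchor_values(self, kerma, blood):
        assert convert_dose(kerma, "air_kerma", "dose_to_blood") == pytest.approx(
            blood, abs=1e-12
        )

    def test_identity_conversion(self):
        assert convert_dose(1.234, "air_kerma", "air_kerma") == 1.234

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_round_trip_invertibility(self, kerma):
        blood = convert_dose(kerma, "air_kerma", "dose_to_blood")
        back = convert_dose(blood, "dose_to_blood", "air_kerma")
        assert back == pytest.approx(kerma, abs=1e-10)

    def test_water_conversion_fails_loudly(self):
        with pytest.raises(CapabilityError):
            convert_dose(2.0, "dose_to_water", "dose_to_blood")
        with pytest.raises(CapabilityError):
            convert_dose(2.0, "air_kerma", "dose_to_water")

    def test_constant_extrapolation_outside_anchors(self):
        table = DEFAULT_CONVERSION_TABLE
        low_factor = table.factor_at(0.5)
        assert low_factor == pytest.approx(2.71 / 2.56)
        high_factor = table.factor_at(9.0)
        assert high_factor == pytest.approx(4.80 / 4.54)

    def test_invalid_tables_rejected(self):
        with pytest.raises(InputError):
            DoseConversionTable(anchors=((1.0, 0.9),))  # factor < 1
        with pytest.raises(InputError):
            DoseConversionTable(anchors=((1.0, 1.1), (1.0, 1.2)))  # not increasing
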