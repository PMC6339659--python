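"""OLS calibration, replicate statistics, inverse prediction, LOB/LOD/LOQ."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfaquant import (
    CalibrationModel,
    fit_calibration,
    limits_method1,
    limits_method2,
    pearson_vs_predicted,
    predict_concentration,
    replicate_stats,
)
from lfaquant.errors import (
    DesignError,
    InsufficientBlanksError,
    InvalidInputError,
    Method2UnavailableError,
    NonInvertibleModelError,
    UndefinedCorrelationError,
)
from conftest import make_measurements


def fit_points(xs, ys, mode="normalized"):
    return fit_calibration(make_measurements(xs, ys, mode), mode)


class TestFitCalibration:
    def test_exact_line(self, toy_line_measurements):
        res = fit_calibration(toy_line_measurements)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_hand_least_squares_oracle(self):
        # (0,0),(1,1),(2,1): normal equations give slope 1/2, intercept 1/6,
        # SSE = 1/6, SST = 2/3, so R^2 = 1 - (1/6)/(2/3) = 3/4
        res = fit_points([0, 1, 2], [0, 1, 1])
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(1 / 6, abs=1e-12)
        assert res.r_squared == pytest.approx(0.75, abs=1e-12)

    def test_single_concentration_is_design_error(self):
        with pytest.raises(DesignError):
            fit_points([5, 5, 5], [1, 2, 3])

    def test_undefined_ratios_collected_as_rejects(self):
        ms = make_measurements([0, 1, 2], [1, 3, 5])
        ms[1].normalized = None
        res = fit_calibration(ms)
        assert res.n_points == 2
        assert len(res.model.rejects) == 1

    def test_all_ratios_rejected_is_design_error(self):
        ms = make_measurements([0, 1], [1, 2])
        for m in ms:
            m.normalized = None
        with pytest.raises(DesignError):
            fit_calibration(ms)

    def test_replicate_table_brackets_mean(self):
        ms = make_measurements([0, 0, 0, 10, 10, 10], [1.0, 1.1, 0.9, 2.0, 2.2, 1.8])
        res = fit_calibration(ms)
        tab = res.per_concentration
        assert (tab["ci_low"] <= tab["mean"]).all()
        assert (tab["mean"] <= tab["ci_high"]).all()
        assert (tab["sd"] >= 0).all()

    def test_parameter_recovery_ratio_level(self):
        """Mean slope bias over 200 seeded simulations stays below 5%."""
        design = np.repeat([0, 1, 20, 40, 60, 80, 100], 5).astype(float)
        slopes = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = 0.5 + 0.02 * design + rng.normal(0, 0.01, design.size)
            slopes.append(fit_points(design, y).slope)
        assert abs(np.mean(slopes) - 0.02) < 0.05 * 0.02


class TestReplicateStats:
    def test_hand_arithmetic(self):
        mean, sd, lo, hi = replicate_stats([1, 2, 3])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)
        # t_{0.975, 2} = 4.303 from the t-table
        assert lo == pytest.approx(2 - 4.303 / np.sqrt(3), abs=1e-3)
        assert hi == pytest.approx(2 + 4.303 / np.sqrt(3), abs=1e-3)

    def test_zero_variance(self):
        mean, sd, lo, hi = replicate_stats([5, 5, 5, 5])
        assert (mean, sd, lo, hi) == (5.0, 0.0, 5.0, 5.0)

    def test_single_value_has_no_sd(self):
        mean, sd, lo, hi = replicate_stats([7.0])
        assert mean == 7.0 and np.isnan(sd) and np.isnan(lo)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            replicate_stats([])


class TestPredictConcentration:
    def test_algebra(self, toy_line_measurements):
        res = fit_calibration(toy_line_measurements)
        assert res.predict_concentration(5.0) == pytest.approx(2.0)
        assert res.predict_concentration(1.0) == pytest.approx(0.0)

    def test_below_blank_is_negative(self, toy_line_measurements):
        res = fit_calibration(toy_line_measurements)
        assert res.predict_concentration(0.5) < 0

    def test_zero_slope_not_invertible(self):
        res = fit_points([0, 1, 2], [1, 1, 1])
        with pytest.raises(NonInvertibleModelError):
            predict_concentration(res, 1.0)


class TestLimitsMethod1:
    def test_hand_arithmetic(self):
        lim = limits_method1([1, 2, 3])
        assert lim.lod_intensity == pytest.approx(5.0)
        assert lim.loq_intensity == pytest.approx(12.0)
        assert lim.lob_intensity is None

    def test_zero_sd_collapses(self):
        lim = limits_method1([2, 2, 2])
        assert lim.lod_intensity == lim.loq_intensity == pytest.approx(2.0)

    def test_concentration_scale_through_inverse_line(self, toy_line_measurements):
        fit = fit_calibration(toy_line_measurements)
        lim = limits_method1([1, 2, 3], fit)
        assert lim.lod_nM == pytest.approx(2.0)
        assert lim.loq_nM == pytest.approx(5.5)

    def test_too_few_blanks(self):
        with pytest.raises(InsufficientBlanksError):
            limits_method1([1.0])


class TestLimitsMethod2:
    def test_hand_arithmetic(self):
        lim = limits_method2([1, 2, 3], [0, 2, 4])  # sd(1 nM) = 2
        assert lim.lob_intensity == pytest.approx(3.645)
        assert lim.lod_intensity == pytest.approx(6.935)
        assert lim.loq_intensity == pytest.approx(12.0)

    def test_zero_one_nM_sd_collapses_lod_to_lob(self):
        lim = limits_method2([1, 2, 3], [2, 2, 2])
        assert lim.lod_intensity == pytest.approx(lim.lob_intensity)

    def test_zero_blank_sd(self):
        lim = limits_method2([2, 2, 2], [1, 2, 3])  # sd(1 nM) = 1
        assert lim.lob_intensity == pytest.approx(2.0)
        assert lim.lod_intensity == pytest.approx(3.645)
        assert lim.loq_intensity == pytest.approx(2.0)

    def test_missing_one_nM_group(self):
        with pytest.raises(Method2UnavailableError):
            limits_method2([1, 2, 3], [1.0])

    def test_model_pulls_one_nM_group_from_data(self):
        ms = make_measurements(
            [0, 0, 0, 1, 1, 1, 10, 10], [1.0, 1.2, 0.8, 1.1, 1.3, 0.9, 2.0, 2.2]
        )
        res = fit_calibration(ms)
        lim = res.detection_limits(method=2)
        assert lim.method == 2 and lim.lob_intensity is not None

    def test_model_without_one_nM_group_unavailable(self):
        ms = make_measurements([0, 0, 10, 10], [1.0, 1.2, 2.0, 2.2])
        res = fit_calibration(ms)
        with pytest.raises(Method2UnavailableError):
            res.detection_limits(method=2)


class TestPearsonVsPredicted:
    def test_exact_line_gives_one(self, toy_line_measurements):
        res = fit_calibration(toy_line_measurements)
        assert res.pearson_r == pytest.approx(1.0)

    def test_r_equals_sqrt_r_squared(self):
        res = fit_points([0, 1, 2], [0, 1, 1])
        assert res.pearson_r == pytest.approx(np.sqrt(0.75), abs=1e-12)

    def test_constant_observed_undefined(self):
        res = fit_points([0, 1, 2], [0, 1, 2])
        flat = make_measurements([0, 1, 2], [1, 1, 1])
        with pytest.raises(UndefinedCorrelationError):
            pearson_vs_predicted(res, flat)


# ---------------------------------------------------------------------------
# property-based invariants


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_pearson_squared_equals_r_squared(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 30)
    x = rng.uniform(0, 100, n)
    x[1] = x[0] + 1.0  # guarantee >= 2 distinct concentrations
    y = rng.normal(0.5 + 0.02 * x, 0.05)
    res = fit_points(x, y)
    assert res.pearson_r**2 == pytest.approx(res.r_squared, abs=1e-9)


@given(
    st.floats(min_value=0.01, max_value=100.0),
    st.integers(min_value=0, max_value=1000),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_scale_equivariance_of_fit_and_limits(k, seed):
    """Multiplying all ratios by k > 0 scales slope/intercept and the
    intensity-scale limits by k but leaves R^2 and all nM limits unchanged."""
    rng = np.random.default_rng(seed)
    x = np.repeat([0.0, 1.0, 20.0, 60.0], 3)
    y = 0.5 + 0.02 * x + rng.normal(0, 0.01, x.size)
    base = fit_points(x, y)
    scaled = fit_points(x, k * y)
    assert scaled.slope == pytest.approx(k * base.slope, rel=1e-9)
    assert scaled.intercept == pytest.approx(k * base.intercept, rel=1e-9)
    assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-9)
    lim_b = base.detection_limits(2)
    lim_s = scaled.detection_limits(2)
    assert lim_s.lod_intensity == pytest.approx(k * lim_b.lod_intensity, rel=1e-9)
    assert lim_s.lod_nM == pytest.approx(lim_b.lod_nM, rel=1e-6, abs=1e-9)
    assert lim_s.lob_nM == pytest.approx(lim_b.lob_nM, rel=1e-6, abs=1e-9)
    assert lim_s.loq_nM == pytest.approx(lim_b.loq_nM, rel=1e-6, abs=1e-9)


@given(st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=12))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_limit_ordering_invariants(blanks):
    """LOD <= LOQ (method 1) and LOB <= LOD (method 2) for any nonneg-sd data."""
    lim1 = limits_method1(blanks)
    assert lim1.lod_intensity <= lim1.loq_intensity + 1e-12
    lim2 = limits_method2(blanks, [b + 0.1 for b in blanks])
    assert lim2.lob_intensity <= lim2.lod_intensity + 1e-12
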