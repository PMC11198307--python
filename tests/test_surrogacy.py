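"""Weighted regression, delta-method R2 CI, classification, formatting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from surrotrial import (classify_surrogacy, format_regression,
                        r2_confidence_interval, weighted_regression)
from surrotrial.errors import (DegenerateDesignError, InsufficientPairsError,
                               UndefinedStatisticError)


def normal_equations_fit(x, y, w):
    """Independent oracle: solve the weighted normal equations directly."""
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ beta
    ybar = (w * y).sum() / w.sum()
    r2 = 1 - (w * resid ** 2).sum() / (w * (y - ybar) ** 2).sum()
    return beta[0], beta[1], r2


def weighted_pearson_r2(x, y, w):
    xbar = (w * x).sum() / w.sum()
    ybar = (w * y).sum() / w.sum()
    cov = (w * (x - xbar) * (y - ybar)).sum()
    return cov ** 2 / ((w * (x - xbar) ** 2).sum() * (w * (y - ybar) ** 2).sum())


def _random_instance(rng, k=None):
    k = k or rng.integers(3, 60)
    x = rng.normal(0, 1, k)
    y = 0.5 * x + rng.normal(0, 1, k)
    w = rng.uniform(500, 30000, k)
    return x, y, w


class TestWeightedRegression:
    def test_collinear_points_give_perfect_fit(self):
        x = np.array([-2.0, -1.0, 0.0, 1.5, 3.0])
        pairs = [(xi, 2 * xi + 1, wi) for xi, wi in zip(x, [1, 7, 2, 9, 4])]
        fit = weighted_regression(pairs)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        y = np.array([-1.0, 0.5, 0.5, 2.0])
        w = np.array([1.0, 2.0, 2.0, 1.0])
        fit = weighted_regression(list(zip(x, y, w)))
        b0, b1, r2 = normal_equations_fit(x, y, w)
        assert fit.intercept == pytest.approx(b0, abs=1e-12)
        assert fit.slope == pytest.approx(b1, abs=1e-12)
        assert fit.r2 == pytest.approx(r2, abs=1e-12)

    def test_equal_weights_reduce_to_simple_regression(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 3.0, 4.0])
        fit_w = weighted_regression(list(zip(x, y, [5.0] * 3)))
        slope, intercept = np.polyfit(x, y, 1)
        assert fit_w.slope == pytest.approx(slope, abs=1e-12)
        assert fit_w.intercept == pytest.approx(intercept, abs=1e-12)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(5)
        x, y, w = _random_instance(rng, 25)
        import statsmodels.api as sm
        model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        fit = weighted_regression(list(zip(x, y, w)))
        assert fit.intercept == pytest.approx(model.params[0], rel=1e-9)
        assert fit.slope == pytest.approx(model.params[1], rel=1e-9)
        assert fit.r2 == pytest.approx(model.rsquared, rel=1e-9)
        lo, hi = model.conf_int()[1]
        assert fit.slope_ci[0] == pytest.approx(lo, rel=1e-9)
        assert fit.slope_ci[1] == pytest.approx(hi, rel=1e-9)

    def test_r2_equals_squared_weighted_correlation(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            x, y, w = _random_instance(rng)
            fit = weighted_regression(list(zip(x, y, w)))
            assert fit.r2 == pytest.approx(weighted_pearson_r2(x, y, w),
                                           abs=1e-9)

    @given(scale=st.floats(0.01, 1000))
    def test_weight_rescaling_invariance(self, scale):
        rng = np.random.default_rng(23)
        x, y, w = _random_instance(rng, 12)
        base = weighted_regression(list(zip(x, y, w)))
        scaled = weighted_regression(list(zip(x, y, w * scale)))
        assert scaled.slope == pytest.approx(base.slope, rel=1e-9)
        assert scaled.intercept == pytest.approx(base.intercept, rel=1e-9)
        assert scaled.r2 == pytest.approx(base.r2, rel=1e-9)
        assert scaled.slope_ci[0] == pytest.approx(base.slope_ci[0], rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDesignError):
            weighted_regression([(1.0, 0.0, 1.0), (1.0, 1.0, 1.0),
                                 (1.0, 2.0, 1.0)])
        with pytest.raises(UndefinedStatisticError):
            weighted_regression([(0.0, 1.0, 1.0), (1.0, 1.0, 1.0),
                                 (2.0, 1.0, 1.0)])
        with pytest.raises(InsufficientPairsError):
            weighted_regression([(0.0, 1.0, 1.0)])

    def test_two_points_have_no_slope_ci(self):
        fit = weighted_regression([(0.0, 0.0, 1.0), (1.0, 0.5, 2.0)])
        assert fit.slope_ci is None
        assert fit.slope == pytest.approx(0.5)


class TestR2ConfidenceInterval:
    def test_boundaries_collapse_to_point(self):
        assert r2_confidence_interval(1.0, 10) == (1.0, 1.0)
        assert r2_confidence_interval(0.0, 10) == (0.0, 0.0)

    def test_too_few_pairs_gives_missing_ci(self):
        assert r2_confidence_interval(0.5, 3) is None

    def test_minimum_supported_size_is_four_pairs(self):
        lo, hi = r2_confidence_interval(0.96, 4)
        assert 0.0 <= lo <= 0.96 <= hi <= 1.0

    @given(r2=st.floats(0.05, 0.95), n1=st.integers(5, 80))
    def test_width_decreases_in_n_pairs(self, r2, n1):
        lo1, hi1 = r2_confidence_interval(r2, n1)
        lo2, hi2 = r2_confidence_interval(r2, n1 + 5)
        width = lambda lo, hi: hi - lo
        # clipping can make widths equal; unclipped widths strictly shrink
        sd = lambda n: math.sqrt(4 * r2 * (1 - r2) ** 2 / (n - 3))
        assert sd(n1 + 5) < sd(n1)
        assert width(lo2, hi2) <= width(lo1, hi1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            r2_confidence_interval(1.2, 10)
        with pytest.raises(ValueError):
            r2_confidence_interval(0.5, 10, level=1.5)


class TestClassification:
    @pytest.mark.parametrize("r2,ci,expected_ci,expected_point", [
        (0.96, (0.81, 1.00), "strong", "strong"),
        (0.76, (0.61, 1.00), "inconclusive", "strong"),
        (0.09, (0.00, 0.26), "weak", "weak"),
        (0.60, (0.22, 0.98), "inconclusive", "moderate"),
        (0.49, (0.14, 0.84), "inconclusive", "weak"),
    ])
    def test_threshold_schemes(self, r2, ci, expected_ci, expected_point):
        label_ci, label_point = classify_surrogacy(r2, ci)
        assert label_ci == expected_ci
        assert label_point == expected_point

    def test_missing_ci_is_inconclusive(self):
        label_ci, label_point = classify_surrogacy(0.9, None)
        assert label_ci == "inconclusive"
        assert label_point == "strong"

    @given(r2=st.floats(0, 1), half=st.floats(0, 0.5))
    def test_strong_and_weak_never_co_occur(self, r2, half):
        ci = (max(0.0, r2 - half), min(1.0, r2 + half))
        label_ci, _ = classify_surrogacy(r2, ci)
        # a single interval cannot satisfy lo > 0.72 and hi < 0.50 at once
        assert label_ci in ("strong", "weak", "inconclusive")
        if label_ci == "strong":
            assert ci[0] > 0.72
        if label_ci == "weak":
            assert ci[1] < 0.50


class TestFormatting:
    @pytest.mark.parametrize("intercept,slope,label,expected", [
        (-0.06, 0.14, "bleeding", "-0.06 + 0.14*log(OR_bleeding)"),
        (0, 1, "x", "0.00 + 1.00*log(OR_x)"),
        (-0.09, -0.11, "bleeding", "-0.09 - 0.11*log(OR_bleeding)"),
        (-0.001, 0.224, "bleeding", "-0.00 + 0.22*log(OR_bleeding)"),
    ])
    def test_two_decimal_formula(self, intercept, slope, label, expected):
        if expected.startswith("-0.00"):
            expected = expected.replace("-0.00", "0.00")
        assert format_regression(intercept, slope, label) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            format_regression(float("nan"), 1.0)
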