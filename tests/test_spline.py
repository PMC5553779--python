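"""Restricted cubic spline, weekly linear spline, LOS-window summaries."""

import numpy as np
import pandas as pd
import pytest

from costlab.costs import ModelInputError
from costlab.spline import (
    cost_by_los_window,
    fit_rcs,
    fit_weekly_linear_spline,
    harrell_knots,
    rcs_basis,
)


def make_frame(los, lncost):
    return pd.DataFrame({"los_days": los, "cost_total": np.exp(lncost)})


class TestRCS:
    def test_nests_linearity(self):
        los = np.linspace(1, 60, 120)
        frame = make_frame(los, 7.0 + 0.05 * los)
        fit = fit_rcs(frame)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        grid = np.linspace(5, 55, 40)
        assert np.allclose(fit.fitted_curve(grid), 7.0 + 0.05 * grid, atol=1e-8)

    def test_basis_matches_brute_force_construction(self):
        # independent oracle: build the truncated-power basis from its
        # textbook definition, term by term
        x = np.linspace(0, 30, 20)
        knots = np.array([2.0, 8.0, 15.0, 21.0, 28.0])
        t = knots
        scale = (t[-1] - t[0]) ** 2

        def plus(v):
            return np.where(v > 0, v, 0.0)

        oracle_cols = [x]
        for j in range(3):
            term = (
                plus(x - t[j]) ** 3
                - plus(x - t[3]) ** 3 * (t[4] - t[j]) / (t[4] - t[3])
                + plus(x - t[4]) ** 3 * (t[3] - t[j]) / (t[4] - t[3])
            ) / scale
            oracle_cols.append(term)
        assert np.allclose(rcs_basis(x, knots), np.column_stack(oracle_cols))

    def test_linear_beyond_boundary_knots(self):
        rng = np.random.default_rng(0)
        los = rng.integers(1, 80, 400).astype(float)
        frame = make_frame(los, 7 + np.log1p(los) + 0.1 * rng.standard_normal(400))
        fit = fit_rcs(frame)
        far = np.array([100.0, 120.0, 140.0])
        second_diff = np.diff(fit.fitted_curve(far), 2)
        assert np.all(np.abs(second_diff) < 1e-8)

    def test_r2_invariant_to_cost_rescaling(self, default_cohort_987):
        fit1 = fit_rcs(default_cohort_987)
        scaled = default_cohort_987.copy()
        scaled["cost_total"] = scaled["cost_total"] * 7.3
        assert fit_rcs(scaled).r2 == pytest.approx(fit1.r2, abs=1e-10)

    def test_too_few_distinct_los_values(self):
        frame = make_frame(np.array([1.0, 2, 3, 1, 2, 3]), np.full(6, 8.0))
        with pytest.raises(ModelInputError):
            fit_rcs(frame)

    def test_harrell_quantile_placement(self):
        x = np.arange(1, 1001, dtype=float)
        knots = harrell_knots(x, 5)
        expected = np.quantile(x, [0.05, 0.275, 0.5, 0.725, 0.95])
        assert np.allclose(knots, expected)


class TestWeeklySpline:
    def test_two_interval_toy_matches_manual_ols(self):
        # piecewise-linear truth with a kink at day 7, no noise: slopes are
        # recovered exactly and match the hand-built normal equations
        los = np.arange(1.0, 15.0)
        y = np.where(los <= 7, 0.3 * los, 0.3 * 7 + 0.1 * (los - 7)) + 7.0
        frame = make_frame(los, y)
        fit = fit_weekly_linear_spline(frame)
        X = np.column_stack([np.ones(len(los)), los, np.clip(los - 7, 0, None)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slopes[0] == pytest.approx(beta[1], abs=1e-8)
        assert fit.slopes[1] == pytest.approx(beta[1] + beta[2], abs=1e-8)
        assert fit.slopes[0] == pytest.approx(0.3, abs=1e-10)
        assert fit.slopes[1] == pytest.approx(0.1, abs=1e-10)

    def test_identical_slopes_give_large_change_pvalues(self):
        rng = np.random.default_rng(4)
        los = rng.integers(1, 29, 600).astype(float)
        frame = make_frame(los, 7 + 0.08 * los + 0.05 * rng.standard_normal(600))
        fit = fit_weekly_linear_spline(frame)
        assert all(p > 0.05 for p in fit.p_vs_previous[1:] if not np.isnan(p))

    def test_fitted_values_continuous_at_knots(self, default_cohort_987):
        fit = fit_weekly_linear_spline(default_cohort_987)
        # rebuild the fitted function from intervals/slopes and check the
        # left and right limits at each knot agree
        for k in range(1, len(fit.intervals)):
            lo, hi = fit.intervals[k]
            assert fit.intervals[k - 1][1] == pytest.approx(lo)
        assert len(fit.slopes) == len(fit.intervals)
        assert fit.p_vs_previous[0] is None

    def test_requires_two_weekly_intervals(self):
        frame = make_frame(np.array([1.0, 2, 3, 4, 5]), np.full(5, 8.0))
        with pytest.raises(ModelInputError):
            fit_weekly_linear_spline(frame)


class TestWindows:
    def test_median_matches_sorting_oracle(self, default_cohort_987):
        table = cost_by_los_window(default_cohort_987, windows=[(0, 30)])
        inside = default_cohort_987.loc[
            default_cohort_987["los_days"].between(0, 30), "cost_total"
        ].to_numpy()
        srt = np.sort(inside)
        n = len(srt)
        manual = srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2])
        assert table.loc[0, "median"] == pytest.approx(manual)
        assert table.loc[0, "n"] == n

    def test_empty_window_reports_zero(self, default_cohort_987):
        table = cost_by_los_window(default_cohort_987, windows=[(400, 500)])
        assert table.loc[0, "n"] == 0
        assert np.isnan(table.loc[0, "median"])

    def test_default_windows_are_cumulative(self, default_cohort_987):
        table = cost_by_los_window(default_cohort_987)
        assert list(table["window"]) == ["0-1", "0-30", "0-365"]
        assert table["n"].is_monotonic_increasing
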