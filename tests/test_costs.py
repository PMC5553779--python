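"""Log-cost regression, Duan smearing, dollar effects, CPI inflation."""

import math

import numpy as np
import pandas as pd
import pytest

from costlab.costs import (
    CPISeries,
    ModelInputError,
    RankDeficiencyError,
    association_test,
    fit_log_cost,
    fit_morbidity_count_cost,
    holm_adjust,
    inflate,
    load_default_cpi,
)


class TestInflate:
    def test_identity_same_year(self):
        cpi = CPISeries({2008: 215.3})
        assert inflate(100.0, 2008, 2008, cpi) == 100.0

    def test_ratio(self):
        cpi = CPISeries({2000: 100.0, 2001: 110.0})
        assert inflate(100.0, 2000, 2001, cpi) == pytest.approx(110.0)

    def test_chaining_equals_direct(self):
        cpi = CPISeries({1999: 166.6, 2008: 215.303, 2015: 237.017})
        via = inflate(inflate(500.0, 1999, 2008, cpi), 2008, 2015, cpi)
        assert via == pytest.approx(inflate(500.0, 1999, 2015, cpi))

    def test_missing_year_raises(self):
        with pytest.raises(LookupError):
            inflate(1.0, 1990, 2015, load_default_cpi())

    def test_nonpositive_index_rejected(self):
        with pytest.raises(ModelInputError):
            CPISeries({2000: 0.0})


class TestSmearing:
    def test_noise_free_cohort_gives_unit_smear(self):
        # exact log-linear data: residuals are zero, smear factor is 1 and
        # the dollar change equals the exact difference of exponentials
        n = 50
        x = np.tile([0, 1], n // 2).astype(float)
        cost = np.exp(7.0 + 0.5 * x)
        frame = pd.DataFrame({"cost_total": cost, "x": x})
        fit = fit_log_cost(frame, covariates=("x",), n_boot=0)
        assert fit.smear.value == pytest.approx(1.0, abs=1e-12)
        expected = math.exp(7.5) - math.exp(7.0)
        assert fit.effects["x"].dollar_change == pytest.approx(expected, rel=1e-10)

    def test_smear_factor_of_symmetric_residuals(self):
        # residuals {ln 2, ln 1/2} alternating around a flat fit -> mean of
        # exponentiated residuals is (2 + 0.5) / 2 = 1.25
        base = np.array([math.log(2), math.log(0.5)] * 20)
        frame = pd.DataFrame(
            {"cost_total": np.exp(5.0 + base), "x": np.zeros(40) + np.tile([0, 1], 20)}
        )
        # x alternates with the residual pattern; use a pure-intercept model
        fit = fit_log_cost(
            frame.assign(const_x=0.0 * frame.x),
            covariates=(),
            n_boot=0,
        )
        assert fit.smear.value == pytest.approx(1.25, rel=1e-12)

    def test_mean_smeared_fitted_matches_mean_observed(self, small_cohort):
        # Duan's estimator reproduces the observed mean exactly when the
        # exponentiated residuals are uncorrelated with the exponentiated
        # linear predictor; a sparse covariate set leaves some exp-scale
        # covariance (omitted stay effects), so the match is approximate
        fit = fit_log_cost(
            small_cohort, covariates=("hypertension", "age"), n_boot=0
        )
        ratio = fit.mean_smeared_fitted / fit.mean_observed
        assert abs(ratio - 1.0) < 0.02


class TestHandComputedOracle:
    def test_six_record_ols_matches_manual_normal_equations(self, toy_cost_frame):
        y = np.log(toy_cost_frame["cost_total"].to_numpy())
        X = np.column_stack(
            [
                np.ones(6),
                toy_cost_frame["exposed"].to_numpy(float),
                toy_cost_frame["age"].to_numpy(float),
            ]
        )
        beta_manual = np.linalg.solve(X.T @ X, X.T @ y)
        smear_manual = float(np.mean(np.exp(y - X @ beta_manual)))

        fit = fit_log_cost(
            toy_cost_frame, covariates=("exposed", "age"), n_boot=0
        )
        assert fit.params["exposed"] == pytest.approx(beta_manual[1], abs=1e-8)
        assert fit.params["age"] == pytest.approx(beta_manual[2], abs=1e-8)
        assert fit.smear.value == pytest.approx(smear_manual, abs=1e-8)

    def test_bootstrap_ci_brackets_estimate(self, toy_cost_frame):
        fit = fit_log_cost(
            toy_cost_frame, covariates=("exposed", "age"), n_boot=200, seed=1
        )
        eff = fit.effects["exposed"]
        assert eff.ci_low <= eff.dollar_change <= eff.ci_high


class TestDollarScale:
    def test_currency_scale_equivariance(self, small_cohort):
        fit1 = fit_log_cost(small_cohort, covariates=("hypertension", "age"), n_boot=0)
        scaled = small_cohort.copy()
        scaled["cost_total"] = scaled["cost_total"] * 3.0
        fit3 = fit_log_cost(scaled, covariates=("hypertension", "age"), n_boot=0)
        assert fit3.effects["hypertension"].dollar_change == pytest.approx(
            3.0 * fit1.effects["hypertension"].dollar_change, rel=1e-9
        )
        # the log-scale coefficient itself is scale invariant
        assert fit3.effects["hypertension"].beta_log == pytest.approx(
            fit1.effects["hypertension"].beta_log, abs=1e-12
        )

    def test_count_model_with_null_effects_is_near_zero(self):
        rng = np.random.default_rng(3)
        n = 4000
        count = rng.integers(0, 4, n).astype(float)
        frame = pd.DataFrame(
            {
                "cost_total": np.exp(8.0 + 0.3 * rng.standard_normal(n)),
                "morbidity_count": count,
                "age": rng.normal(70, 10, n),
            }
        )
        est = fit_morbidity_count_cost(frame, n_boot=0)
        assert abs(est.dollar_change) < 150.0  # ~2 SE around zero
        assert est.p_value > 0.01


class TestValidation:
    def test_nonpositive_cost_rejected(self, toy_cost_frame):
        bad = toy_cost_frame.copy()
        bad.loc[0, "cost_total"] = 0.0
        with pytest.raises(ModelInputError):
            fit_log_cost(bad, covariates=("exposed",), n_boot=0)

    def test_rank_deficiency_names_column(self, toy_cost_frame):
        dup = toy_cost_frame.assign(exposed_copy=toy_cost_frame["exposed"])
        with pytest.raises(RankDeficiencyError, match="exposed"):
            fit_log_cost(dup, covariates=("exposed", "exposed_copy"), n_boot=0)

    def test_single_level_exposure_rejected(self, toy_cost_frame):
        flat = toy_cost_frame.assign(exposed=1)
        with pytest.raises(ModelInputError):
            association_test(flat, "exposed")


def test_holm_adjustment_orders_and_caps():
    adjusted = holm_adjust({"a": 0.01, "b": 0.04, "c": 0.3})
    assert adjusted["a"] == pytest.approx(0.03)
    assert adjusted["b"] == pytest.approx(0.08)
    assert adjusted["c"] == pytest.approx(0.3)
    assert all(v <= 1.0 for v in adjusted.values())
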