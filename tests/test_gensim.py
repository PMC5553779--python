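"""Generational Monte Carlo simulation and Welch's test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from costlab.cohort import ConfigError
from costlab.gensim import (
    BACKSOLVED_BASE_POPULATION,
    GenSimConfig,
    assign_costs_from_reference,
    cohort_size,
    draw_generation_cohort,
    run_generation_sim,
    welch_test,
)


class TestCohortSize:
    def test_zero_growth_is_rate_times_years(self):
        assert cohort_size(1e6, 0.0, 12e-5, 10) == 1200

    def test_single_year(self):
        assert cohort_size(5e6, 0.0094, 12e-5, 1) == round(5e6 * 12e-5)

    def test_geometric_sum_reproduces_published_century_total(self):
        # independent oracle: explicit year-by-year loop
        total = 0.0
        pop = BACKSOLVED_BASE_POPULATION
        for _ in range(100):
            total += pop * 12e-5
            pop *= 1.0094
        n = cohort_size(BACKSOLVED_BASE_POPULATION, 0.0094, 12e-5, 100)
        assert n == round(total)
        assert abs(n - 717_727) / 717_727 < 0.001

    def test_monotone_in_every_argument(self):
        base = cohort_size(1e6, 0.01, 1e-4, 50)
        assert cohort_size(2e6, 0.01, 1e-4, 50) > base
        assert cohort_size(1e6, 0.02, 1e-4, 50) > base
        assert cohort_size(1e6, 0.01, 2e-4, 50) > base
        assert cohort_size(1e6, 0.01, 1e-4, 60) > base

    def test_invalid_arguments(self):
        with pytest.raises(ConfigError):
            cohort_size(0, 0.01, 1e-4, 10)


class TestDrawCohort:
    def test_ages_within_theoretical_bounds(self):
        cfg = GenSimConfig(per_replicate_n=20_000)
        sample = draw_generation_cohort(cfg, np.random.default_rng(0))
        assert sample["age"].between(18, 126).all()
        # truncation barely shifts the mean at these bounds
        assert sample["age"].mean() == pytest.approx(70.0, abs=0.35)

    def test_zero_prevalence_gives_no_hypertensives(self):
        cfg = GenSimConfig(hyp_prev=0.0, per_replicate_n=5000)
        sample = draw_generation_cohort(cfg, np.random.default_rng(1))
        assert sample["hypertension"].sum() == 0

    def test_hypertension_frequency(self):
        cfg = GenSimConfig(per_replicate_n=50_000)
        sample = draw_generation_cohort(cfg, np.random.default_rng(2))
        assert sample["hypertension"].mean() == pytest.approx(0.77, abs=0.01)


def null_reference(n=4000, seed=0):
    """Reference cohort with no hypertension-cost association."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.normal(70, 13, n).clip(18, 99),
            "hypertension": (rng.random(n) < 0.67).astype(float),
            "cost_total": np.exp(9.0 + 0.5 * rng.standard_normal(n)),
        }
    )


class TestGenerationSim:
    def test_reproducible_given_seed(self):
        cfg = GenSimConfig(n_replicates=5, per_replicate_n=2000, seed=9)
        ref = null_reference()
        a = run_generation_sim(cfg, ref)
        b = run_generation_sim(cfg, ref)
        assert a == b

    def test_null_reference_gives_null_mean_effect(self):
        cfg = GenSimConfig(n_replicates=40, per_replicate_n=5000, seed=3)
        result = run_generation_sim(cfg, null_reference(8000))
        se = result.sd_across_replicates / np.sqrt(result.n_replicates)
        assert abs(result.mean_dollar_increase) < 4 * se + 50.0

    def test_missing_stratum_rejected(self):
        cfg = GenSimConfig(n_replicates=2, per_replicate_n=500)
        ref = null_reference()
        ref["hypertension"] = 1.0
        with pytest.raises(ConfigError):
            run_generation_sim(cfg, ref)

    def test_cost_assignment_resamples_observed_values(self):
        ref = null_reference(2000)
        rng = np.random.default_rng(5)
        cfg = GenSimConfig(per_replicate_n=3000)
        sample = draw_generation_cohort(cfg, rng)
        withcost = assign_costs_from_reference(sample, ref, rng)
        observed = np.unique(np.round(np.log(ref["cost_total"]), 10))
        drawn = np.unique(np.round(np.log(withcost["cost_total"]), 10))
        assert np.isin(drawn, observed).all()


class TestWelch:
    def test_identical_summaries(self):
        t, df, p = welch_test(5.0, 2.0, 30, 5.0, 2.0, 30)
        assert t == 0.0 and p == 1.0

    def test_equal_n_equal_var_reduces_to_student(self):
        t, df, p = welch_test(10.0, 4.0, 25, 12.0, 4.0, 25)
        t_student = (10.0 - 12.0) / np.sqrt(4.0 / 25 + 4.0 / 25)
        assert t == pytest.approx(t_student)
        assert df == pytest.approx(48.0)

    def test_matches_scipy_summary_test(self):
        t, df, p = welch_test(10.0, 4.0, 30, 12.0, 9.0, 40)
        ref = stats.ttest_ind_from_stats(
            10.0, 2.0, 30, 12.0, 3.0, 40, equal_var=False
        )
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_convention(self):
        assert welch_test(1.0, 0.0, 5, 1.0, 0.0, 5)[2] == 1.0
        assert welch_test(1.0, 0.0, 5, 2.0, 0.0, 5)[2] == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ConfigError):
            welch_test(1.0, 1.0, 1, 2.0, 1.0, 5)
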