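"""Relative-risk models for dichotomized stay outcomes.

Prolonged stay is defined as strictly more than 7 days in hospital (a
stay of exactly one week counts as short); in-hospital death is the other
dichotomous outcome of interest.  Relative risks are estimated with a
binomial GLM with log link ("log-binomial" regression), which returns
risk ratios directly.  Log-binomial likelihoods are notoriously fragile
when the outcome is common — the linear predictor wants to cross zero —
so on nonconvergence the fit falls back automatically to the modified
Poisson estimator (Poisson GLM with robust HC1 variance), which targets
the same RR; the result records which route was used.

Also provides a calendar-year trend test for admission characteristics
(binomial regression of the characteristic on year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costs import ModelInputError, _check_rank, _design

__all__ = ["RRResult", "TrendResult", "fit_rr", "rr_from_counts", "trend_test"]


@dataclass(frozen=True)
class RRResult:
    """Relative risk with Wald 95% CI and provenance of the estimator."""

    exposure: str
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted_for: tuple[str, ...]
    model_used: str  # "log-binomial" or "poisson-robust-fallback"

    def __post_init__(self) -> None:
        if not (self.rr > 0 and self.ci_low <= self.rr <= self.ci_high):
            raise ModelInputError("inconsistent RR / CI ordering")


@dataclass(frozen=True)
class TrendResult:
    """Calendar-trend test outcome for a binary characteristic."""

    characteristic: str
    direction: str  # "increase" or "decrease"
    slope: float
    p_value: float


def _binary_check(values: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    levels = set(np.unique(v))
    if not levels <= {0.0, 1.0} or len(levels) < 2:
        raise ModelInputError(
            f"{name!r} must be binary with both levels present (got levels {sorted(levels)})"
        )
    return v


def fit_rr(
    cohort: pd.DataFrame,
    outcome: str = "los_gt7",
    exposure: str = "hypertension",
    adjust: Sequence[str] = ("age",),
) -> RRResult:
    """Adjusted relative risk of a binary outcome for a binary exposure.

    Fits a log-link binomial GLM of ``outcome`` on ``exposure`` plus the
    adjustment covariates; on convergence failure, refits as a modified
    Poisson model with HC1 robust variance.  Returns the exposure RR with
    its Wald 95% CI.
    """
    if outcome == exposure:
        raise ModelInputError("outcome and exposure must differ")
    y = _binary_check(cohort[outcome], outcome)
    _binary_check(cohort[exposure], exposure)
    covariates = (exposure, *tuple(adjust))
    X = _design(cohort, covariates)
    _check_rank(X, covariates)

    start = np.zeros(X.shape[1])
    start[0] = np.log(max(np.mean(y), 1e-6))
    model_used = "log-binomial"
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(sm.families.links.Log())).fit(
                start_params=start, maxiter=200
            )
            mu = res.predict(X)
            if (not res.converged) or np.any(mu >= 1.0) or np.any(~np.isfinite(res.bse)):
                res = None
        except Exception:
            res = None
        if res is None:
            model_used = "poisson-robust-fallback"
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC1", maxiter=200)
            if not res.converged:
                raise ModelInputError(
                    f"relative-risk model for {exposure!r} failed to converge "
                    "under both the log-binomial and modified Poisson routes"
                )

    beta = float(res.params[1])
    se = float(res.bse[1])
    return RRResult(
        exposure=exposure,
        rr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(res.pvalues[1]),
        adjusted_for=tuple(adjust),
        model_used=model_used,
    )


def rr_from_counts(a: int, b: int, c: int, d: int) -> float:
    """Unadjusted RR from a 2x2 table: exposed a/(a+b) vs unexposed c/(c+d)."""
    if min(a + b, c + d) == 0 or c == 0:
        raise ModelInputError("degenerate 2x2 table")
    return (a / (a + b)) / (c / (c + d))


def trend_test(
    cohort: pd.DataFrame,
    characteristic: str,
    year_column: str = "admission_year",
) -> TrendResult:
    """Test for a monotone calendar-year trend in a binary characteristic.

    Binomial regression of the characteristic on calendar year; returns
    the slope sign and the Wald p-value.  Requires at least two distinct
    years and a non-constant characteristic.
    """
    years = np.asarray(cohort[year_column], dtype=float)
    if len(np.unique(years)) < 2:
        raise ModelInputError("trend test needs at least two distinct years")
    y = _binary_check(cohort[characteristic], characteristic)
    X = np.column_stack([np.ones_like(years), years - years.mean()])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    if not res.converged or not np.all(np.isfinite(res.bse)):
        raise ModelInputError(f"degenerate trend fit for {characteristic!r}")
    slope = float(res.params[1])
    return TrendResult(
        characteristic=characteristic,
        direction="increase" if slope > 0 else "decrease",
        slope=slope,
        p_value=float(res.pvalues[1]),
    )
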