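"""Dollar-scale cost-effect estimation.

Hospital cost data are strongly right-skewed, so association models are
fit by ordinary least squares on ln(cost) with heteroscedasticity-robust
(HC1 sandwich) standard errors.  Coefficients are translated back to the
dollar scale with Duan's smearing estimator — the mean of exponentiated
in-sample residuals — which corrects the retransformation bias of
``exp(fitted)`` without assuming normal errors:

    E[cost | x] ≈ smear · exp(x'β),   smear = (1/n) Σ exp(e_i).

The reported ``dollar_change`` of a covariate is an average marginal
effect: the cohort-average difference between smeared predicted costs
with the covariate set to 1 versus 0 (or incremented by one unit for a
numeric covariate such as the morbidity count), all other covariates held
at their observed values.  Confidence intervals for dollar changes come
from a seeded nonparametric bootstrap of the whole pipeline; p-values are
robust Wald tests of the log-scale coefficient.

Also provides CPI-based inflation adjustment of historical cost records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CPISeries",
    "EffectEstimate",
    "SmearFactor",
    "LogCostFit",
    "load_default_cpi",
    "inflate",
    "fit_log_cost",
    "fit_morbidity_count_cost",
    "association_test",
    "holm_adjust",
]


class ModelInputError(ValueError):
    """Raised for invalid model input (nonpositive costs, bad columns...)."""


class RankDeficiencyError(ModelInputError):
    """Design matrix is not full rank; names the offending columns."""


# ---------------------------------------------------------------------------
# CPI inflation


@dataclass(frozen=True)
class CPISeries:
    """Consumer-price-index series: calendar year -> index value (> 0)."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        for year, v in self.values.items():
            if not v > 0:
                raise ModelInputError(f"CPI index for {year} must be positive")

    def __getitem__(self, year: int) -> float:
        try:
            return self.values[int(year)]
        except KeyError:
            raise LookupError(f"year {year} not present in CPI series") from None

    @classmethod
    def from_csv(cls, path) -> "CPISeries":
        df = pd.read_csv(path, comment="#")
        year_col, value_col = df.columns[:2]
        return cls(values=dict(zip(df[year_col].astype(int), df[value_col].astype(float))))


def load_default_cpi() -> CPISeries:
    """US CPI-U annual averages, 1999-2015 (reference series shipped as data)."""
    with resources.files("costlab").joinpath("data/cpi_us_1999_2015.csv").open("r") as fh:
        return CPISeries.from_csv(fh)


def inflate(amount: float, from_year: int, to_year: int, cpi: CPISeries) -> float:
    """Rescale a historical amount to ``to_year`` dollars via CPI ratio."""
    return amount * cpi[to_year] / cpi[from_year]


# ---------------------------------------------------------------------------
# log-cost OLS with smearing


@dataclass(frozen=True)
class SmearFactor:
    """Duan smearing factor: mean of exponentiated OLS residuals."""

    value: float

    def __post_init__(self) -> None:
        if not self.value >= 0:
            raise ModelInputError("smear factor must be non-negative")


@dataclass(frozen=True)
class EffectEstimate:
    """One covariate's effect on cost, on both scales."""

    covariate: str
    beta_log: float
    se_robust: float
    dollar_change: float
    p_value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class LogCostFit:
    """Full result of a smeared log-cost regression."""

    outcome: str
    covariates: tuple[str, ...]
    effects: Mapping[str, EffectEstimate]
    smear: SmearFactor
    r2: float
    nobs: int
    params: Mapping[str, float]
    mean_observed: float
    mean_smeared_fitted: float
    p_holm: Mapping[str, float] = field(default_factory=dict)


def _design(cohort: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    cols.extend(np.asarray(cohort[c], dtype=float) for c in covariates)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report the columns whose removal leaves the rank unchanged
        bad = []
        for j in range(1, X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j - 1])
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear column(s): {bad or names}"
        )


def _dollar_change(
    X: np.ndarray,
    beta: np.ndarray,
    smear: float,
    col: int,
    binary: bool,
) -> float:
    X1 = X.copy()
    X0 = X.copy()
    if binary:
        X1[:, col] = 1.0
        X0[:, col] = 0.0
    else:
        X1[:, col] = X[:, col] + 1.0
    return float(smear * np.mean(np.exp(X1 @ beta) - np.exp(X0 @ beta)))


def fit_log_cost(
    cohort: pd.DataFrame,
    outcome: str = "cost_total",
    covariates: Sequence[str] = ("hypertension", "age"),
    n_boot: int = 1000,
    seed: int | None = 0,
    holm: bool = False,
) -> LogCostFit:
    """OLS of ln(outcome) on covariates, with smeared dollar effects.

    Parameters
    ----------
    cohort
        Cohort DataFrame; ``outcome`` must be strictly positive.
    covariates
        Column names entering the model (binary flags and/or numeric
        covariates such as age or morbidity count).
    n_boot
        Bootstrap replicates for the dollar-change percentile CI; 0
        disables the bootstrap (CIs reported as None).
    holm
        Optionally attach Holm-adjusted p-values across the covariates
        (off by default, matching single-test reporting at alpha = 0.05).

    Returns
    -------
    LogCostFit
        Per-covariate :class:`EffectEstimate`, the Duan
        :class:`SmearFactor`, and fit diagnostics.
    """
    y_raw = np.asarray(cohort[outcome], dtype=float)
    if np.any(~np.isfinite(y_raw)) or np.any(y_raw <= 0):
        raise ModelInputError(f"{outcome} must be finite and strictly positive")
    covariates = tuple(covariates)
    X = _design(cohort, covariates)
    _check_rank(X, covariates)
    y = np.log(y_raw)

    res = sm.OLS(y, X).fit(cov_type="HC1")
    beta = np.asarray(res.params)
    resid = y - X @ beta
    smear = float(np.mean(np.exp(resid)))
    binary = {
        c: set(np.unique(np.asarray(cohort[c], dtype=float))) <= {0.0, 1.0}
        for c in covariates
    }

    point = {
        c: _dollar_change(X, beta, smear, j + 1, binary[c])
        for j, c in enumerate(covariates)
    }

    ci: dict[str, tuple[Optional[float], Optional[float]]]
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = {c: np.empty(n_boot) for c in covariates}
        n = len(y)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb, yb = X[idx], y[idx]
            beta_b, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
            smear_b = float(np.mean(np.exp(yb - Xb @ beta_b)))
            for j, c in enumerate(covariates):
                draws[c][b] = _dollar_change(Xb, beta_b, smear_b, j + 1, binary[c])
        ci = {
            c: tuple(np.percentile(draws[c], [2.5, 97.5])) for c in covariates
        }
    else:
        ci = {c: (None, None) for c in covariates}

    effects = {}
    for j, c in enumerate(covariates):
        effects[c] = EffectEstimate(
            covariate=c,
            beta_log=float(beta[j + 1]),
            se_robust=float(res.bse[j + 1]),
            dollar_change=point[c],
            p_value=float(res.pvalues[j + 1]),
            ci_low=ci[c][0],
            ci_high=ci[c][1],
        )

    p_holm = (
        holm_adjust({c: e.p_value for c, e in effects.items()}) if holm else {}
    )
    fitted_cost = smear * np.exp(X @ beta)
    return LogCostFit(
        outcome=outcome,
        covariates=covariates,
        effects=effects,
        smear=SmearFactor(smear),
        r2=float(res.rsquared),
        nobs=len(y),
        params={"const": float(beta[0]), **{c: float(beta[j + 1]) for j, c in enumerate(covariates)}},
        mean_observed=float(np.mean(y_raw)),
        mean_smeared_fitted=float(np.mean(fitted_cost)),
        p_holm=p_holm,
    )


def fit_morbidity_count_cost(
    cohort: pd.DataFrame,
    outcome: str = "cost_total",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> EffectEstimate:
    """Age-adjusted smeared dollar change per one additional morbidity."""
    fit = fit_log_cost(
        cohort,
        outcome=outcome,
        covariates=("morbidity_count", "age"),
        n_boot=n_boot,
        seed=seed,
    )
    return fit.effects["morbidity_count"]


def association_test(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str = "cost_total",
    adjust: Sequence[str] = ("age",),
) -> float:
    """Robust Wald p-value for a binary exposure in an adjusted log-cost model."""
    levels = set(np.unique(np.asarray(cohort[exposure], dtype=float)))
    if len(levels) < 2:
        raise ModelInputError(f"exposure {exposure!r} has a single level")
    fit = fit_log_cost(
        cohort, outcome=outcome, covariates=(exposure, *adjust), n_boot=0
    )
    return fit.effects[exposure].p_value


def holm_adjust(pvalues: Mapping[str, float]) -> dict[str, float]:
    """Holm step-down multiple-testing adjustment."""
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted = {}
    running = 0.0
    for rank, (name, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adjusted[name] = running
    return adjusted
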