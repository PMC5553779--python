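"""Cohort ingest, validation and summarization.

Cohorts travel as UTF-8 comma-separated text with a required header; the
column dictionary is the one produced by the synthetic generator (see
``COLUMN_DICTIONARY``).  Ingest applies the study's inclusion rules —
adults only, and a discharge is kept only when a positive total cost was
recorded — and reports the exclusion bookkeeping.  ``summarize`` produces
the standard sample-characteristics table (percentages, median with range
for the continuous measures, per-category morbidity prevalence).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import MORBIDITY_KEYS, format_codes, parse_codes

__all__ = [
    "IngestError",
    "IngestReport",
    "CohortSummary",
    "ingest",
    "summarize",
    "write_cohort_csv",
    "read_cohort_csv",
    "COLUMN_DICTIONARY",
]

log = logging.getLogger("costlab")

#: Column dictionary for cohort CSV files.
COLUMN_DICTIONARY = {
    "id": "discharge identifier (integer)",
    "age": "age at admission, years (integer, >= 18 after ingest)",
    "sex": "M or F",
    "admission_year": "calendar year of admission (ISO year)",
    "codes": "';'-separated ICD codes; the MRDx code is suffixed with '*'",
    **{k: f"morbidity flag: {k} (bool)" for k in MORBIDITY_KEYS},
    "morbidity_count": "number of flagged morbidity categories",
    "any_morbidity": "morbidity_count >= 1",
    "los_days": "length of stay, whole days >= 1",
    "los_gt7": "stay strictly longer than 7 days (bool)",
    "died": "in-hospital death (bool)",
    "surgery": "surgical management (bool)",
    "cost_diagnostic": "diagnostic-services cost, USD at cost_year",
    "cost_acute": "acute-care cost, USD at cost_year",
    "cost_rehab": "rehabilitation cost, USD at cost_year",
    "cost_total": "total cost, USD at cost_year (sum of the three parts)",
    "cost_year": "dollar year of the cost columns",
    "nihss_ge15": "admission NIHSS >= 15 (optional; blank when unmeasured)",
    "mrs_poor": "discharge mRS 3-5 (optional; blank when unmeasured or died)",
}

REQUIRED_COLUMNS = ("age", "los_days", "cost_total")


class IngestError(ValueError):
    """Unreadable or schema-violating input file."""


@dataclass(frozen=True)
class IngestReport:
    """Bookkeeping of one ingest pass."""

    n_read: int
    n_excluded_missing_cost: int
    n_excluded_age: int
    n_excluded_malformed: int
    n_retained: int
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        expected = (
            self.n_read
            - self.n_excluded_missing_cost
            - self.n_excluded_age
            - self.n_excluded_malformed
        )
        if self.n_retained != expected:
            raise IngestError("ingest counts do not add up")


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort DataFrame as CSV (codes serialized to text)."""
    out = cohort.copy()
    if "codes" in out.columns and len(out) and not isinstance(out["codes"].iloc[0], str):
        out["codes"] = out["codes"].map(format_codes)
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, restoring typed columns."""
    df = pd.read_csv(path)
    if "codes" in df.columns:
        df["codes"] = df["codes"].fillna("").map(parse_codes)
    for col in ("nihss_ge15", "mrs_poor"):
        if col in df.columns:
            df[col] = df[col].astype("boolean")
    for col in df.columns:
        if col in MORBIDITY_KEYS or col in ("any_morbidity", "los_gt7", "died", "surgery"):
            df[col] = df[col].astype(bool)
    return df


def ingest(
    path,
    strict: bool = False,
    min_age: float = 18.0,
) -> tuple[pd.DataFrame, IngestReport]:
    """Read, validate and filter a discharge file.

    Exclusion rules: rows with missing or nonpositive total cost are
    dropped (and counted), as are ages below ``min_age``; malformed rows
    are logged with their line number and skipped, or fatal under
    ``strict=True``.

    Returns the retained cohort and an :class:`IngestReport`.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc
    if df.empty and not df.columns.size:
        raise IngestError(f"{path} is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"{path} lacks required column(s): {missing}")

    n_read = len(df)
    notes: list[str] = []

    age = pd.to_numeric(df["age"], errors="coerce")
    los = pd.to_numeric(df["los_days"], errors="coerce")
    cost = pd.to_numeric(df["cost_total"], errors="coerce")

    malformed = age.isna() | los.isna() | (los < 1)
    if malformed.any():
        lines = (np.flatnonzero(malformed) + 2).tolist()  # +2: header + 1-basing
        msg = f"{int(malformed.sum())} malformed row(s) at line(s) {lines[:20]}"
        if strict:
            raise IngestError(msg)
        log.warning("ingest: %s (skipped)", msg)
        notes.append(msg)

    missing_cost = ~malformed & (cost.isna() | (cost <= 0))
    underage = ~malformed & ~missing_cost & (age < min_age)
    keep = ~(malformed | missing_cost | underage)

    cohort = df.loc[keep].reset_index(drop=True).copy()
    if "codes" in cohort.columns and len(cohort) and isinstance(cohort["codes"].iloc[0], str):
        cohort["codes"] = cohort["codes"].map(parse_codes)
    if "los_gt7" not in cohort.columns:
        cohort["los_gt7"] = pd.to_numeric(cohort["los_days"]) > 7

    report = IngestReport(
        n_read=n_read,
        n_excluded_missing_cost=int(missing_cost.sum()),
        n_excluded_age=int(underage.sum()),
        n_excluded_malformed=int(malformed.sum()),
        n_retained=len(cohort),
        notes=tuple(notes),
    )
    log.info(
        "ingest: read %d, excluded %d (missing cost) + %d (age) + %d (malformed), retained %d",
        report.n_read,
        report.n_excluded_missing_cost,
        report.n_excluded_age,
        report.n_excluded_malformed,
        report.n_retained,
    )
    return cohort, report


@dataclass(frozen=True)
class CohortSummary:
    """Sample-characteristics summary (percentages kept unrounded)."""

    n: int
    pct_male: Optional[float]
    median_age: float
    age_range: tuple[float, float]
    median_los: float
    los_range: tuple[float, float]
    pct_died: Optional[float]
    pct_surgery: Optional[float]
    pct_any_morbidity: Optional[float]
    morbidity_pct: dict
    median_cost_total: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSummary":
        d = dict(d)
        d["age_range"] = tuple(d["age_range"])
        d["los_range"] = tuple(d["los_range"])
        return cls(**d)


def _pct(series) -> Optional[float]:
    return float(100.0 * np.mean(np.asarray(series, dtype=float)))


def summarize(cohort: pd.DataFrame) -> CohortSummary:
    """Sample-characteristics table for a cohort."""
    if len(cohort) == 0:
        raise IngestError("cannot summarize an empty cohort")
    age = np.asarray(cohort["age"], float)
    los = np.asarray(cohort["los_days"], float)
    return CohortSummary(
        n=len(cohort),
        pct_male=_pct(cohort["sex"].eq("M")) if "sex" in cohort else None,
        median_age=float(np.median(age)),
        age_range=(float(age.min()), float(age.max())),
        median_los=float(np.median(los)),
        los_range=(float(los.min()), float(los.max())),
        pct_died=_pct(cohort["died"]) if "died" in cohort else None,
        pct_surgery=_pct(cohort["surgery"]) if "surgery" in cohort else None,
        pct_any_morbidity=_pct(cohort["any_morbidity"])
        if "any_morbidity" in cohort
        else None,
        morbidity_pct={
            k: _pct(cohort[k]) for k in MORBIDITY_KEYS if k in cohort.columns
        },
        median_cost_total=float(np.median(np.asarray(cohort["cost_total"], float))),
    )


def configure_logging(verbose: bool = False, logfile=None) -> None:
    """One-line-per-stage structured logging to stderr (and optional file)."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
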