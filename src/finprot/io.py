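"""Reading, harmonizing, and validating household survey microdata.

Survey files arrive as delimited text with survey-specific column names and
conventions (some fields reported per month). A :class:`DialectMap` carries
the mapping onto the canonical household schema; :func:`load_survey` applies
it, annualizes monthly fields, and drops (but counts) rows that cannot be
parsed. :func:`validate_records` enforces the hard record invariants and
:func:`rebase_currency` converts all monetary fields to a common price year
with a CPI series.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

#: Canonical column order of a harmonized household table.
REQUIRED_FIELDS = (
    "household_id",
    "survey_id",
    "wave_year",
    "urban",
    "province",
    "family_size",
    "income_total",
    "consumption_total",
    "food_expenditure",
    "oop_health_expenditure",
    "weight",
)

#: Fields holding currency amounts (rebased by CPI, scaled in tests, etc.).
MONETARY_FIELDS = (
    "income_total",
    "consumption_total",
    "food_expenditure",
    "oop_health_expenditure",
)

_NUMERIC_FIELDS = ("wave_year", "urban", "family_size", "weight") + MONETARY_FIELDS

MONTHS_PER_YEAR = 12


class SurveyLoadError(ValueError):
    """Raised when a survey file cannot be mapped onto the canonical schema."""


@dataclasses.dataclass(frozen=True)
class DialectMap:
    """Column-name mapping from one survey's file layout to the canonical schema.

    ``column_map`` maps *source* column names to canonical field names and must
    cover every canonical field. ``monthly_fields`` names canonical fields the
    source reports per month; they are annualized (x12) on load. ``notes``
    records concept differences between surveys (e.g. whether supplements or
    exercise spending is counted as out-of-pocket health expenditure); they are
    documentation only and never reconciled numerically.
    """

    survey_id: str
    column_map: Mapping[str, str]
    monthly_fields: frozenset[str] = frozenset()
    notes: str = ""

    def __post_init__(self) -> None:
        mapped = set(self.column_map.values())
        missing = [f for f in REQUIRED_FIELDS if f not in mapped]
        if missing:
            raise SurveyLoadError(
                f"dialect {self.survey_id!r} does not map required field(s): "
                + ", ".join(missing)
            )
        unknown = self.monthly_fields - set(REQUIRED_FIELDS)
        if unknown:
            raise SurveyLoadError(
                f"dialect {self.survey_id!r} marks unknown monthly field(s): "
                + ", ".join(sorted(unknown))
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "DialectMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            survey_id=raw["survey_id"],
            column_map=dict(raw["column_map"]),
            monthly_fields=frozenset(raw.get("monthly_fields", [])),
            notes=raw.get("notes", ""),
        )


def identity_dialect(survey_id: str = "canonical") -> DialectMap:
    """Dialect for files already written with canonical column names."""
    return DialectMap(survey_id=survey_id, column_map={f: f for f in REQUIRED_FIELDS})


@dataclasses.dataclass(frozen=True)
class CpiSeries:
    """Consumer-price-index series on a common base, with a reference year.

    Rebasing multiplies amounts by ``index[reference_year] / index[wave_year]``.
    """

    index: Mapping[int, float]
    reference_year: int

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.index.values()):
            raise ValueError("CPI index values must be positive")
        if self.reference_year not in self.index:
            raise ValueError(
                f"reference year {self.reference_year} missing from CPI series"
            )

    def factor(self, year: int) -> float:
        if year not in self.index:
            raise KeyError(f"CPI series has no index value for year {year}")
        return self.index[self.reference_year] / self.index[year]

    @classmethod
    def from_file(cls, path: str | Path) -> "CpiSeries":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            index={int(k): float(v) for k, v in raw["index"].items()},
            reference_year=int(raw["reference_year"]),
        )


@dataclasses.dataclass
class LoadReport:
    """Row accounting for one :func:`load_survey` call."""

    survey_id: str
    n_source_rows: int = 0
    n_dropped_missing: int = 0
    n_loaded: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ValidationReport:
    """Per-rule counts from :func:`validate_records`.

    Rows violating hard invariants are removed; ``food_exceeds_consumption``
    rows are kept but counted (capacity to pay then turns nonpositive and is
    handled by the indicator rules downstream).
    """

    n_input: int = 0
    negative_amount: int = 0
    family_size_lt_1: int = 0
    nonpositive_weight: int = 0
    food_exceeds_consumption: int = 0
    n_valid: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.readline()
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t|").delimiter
    except csv.Error:
        return ","


def load_survey(
    path: str | Path,
    dialect: DialectMap,
    delimiter: str | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Read a delimited survey file and harmonize it onto the canonical schema.

    Returns the harmonized table plus a :class:`LoadReport`. Rows with a
    missing or unparseable required value are dropped and counted; a source
    column named by the dialect but absent from the header is a hard error.
    """
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in dialect.column_map if c not in raw.columns]
    if missing_cols:
        raise SurveyLoadError(
            f"survey file {path} lacks mapped column(s): " + ", ".join(missing_cols)
        )

    df = raw[list(dialect.column_map)].rename(columns=dict(dialect.column_map))
    df = df[list(REQUIRED_FIELDS)]
    report = LoadReport(survey_id=dialect.survey_id, n_source_rows=len(df))

    parsed = {
        col: pd.to_numeric(df[col].replace("", None), errors="coerce")
        for col in _NUMERIC_FIELDS
    }
    ok = pd.DataFrame(parsed).notna().all(axis=1) & (df["household_id"] != "")
    report.n_dropped_missing = int((~ok).sum())
    df = df.loc[ok].copy()
    for col in _NUMERIC_FIELDS:
        # parse from text with the exact (round-trip) converter, not the fast one
        df[col] = df[col].astype(float)

    for col in ("wave_year", "urban"):
        df[col] = df[col].astype(int)
    for field in dialect.monthly_fields:
        df[field] = df[field] * MONTHS_PER_YEAR

    report.n_loaded = len(df)
    df = df.reset_index(drop=True)
    return df, report


def validate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, ValidationReport]:
    """Enforce hard record invariants; flag (keep) food > consumption rows."""
    report = ValidationReport(n_input=len(records))
    df = records.copy()

    # income may legitimately be negative (net losses); only expenditures are signed
    neg = (
        (df["consumption_total"] < 0)
        | (df["food_expenditure"] < 0)
        | (df["oop_health_expenditure"] < 0)
    )
    small_family = df["family_size"] < 1
    bad_weight = df["weight"] <= 0
    report.negative_amount = int(neg.sum())
    report.family_size_lt_1 = int((small_family & ~neg).sum())
    report.nonpositive_weight = int((bad_weight & ~neg & ~small_family).sum())

    keep = ~(neg | small_family | bad_weight)
    df = df.loc[keep].copy()
    flag = df["food_expenditure"] > df["consumption_total"]
    df["food_exceeds_consumption"] = flag
    report.food_exceeds_consumption = int(flag.sum())
    report.n_valid = len(df)
    return df.reset_index(drop=True), report


def rebase_currency(records: pd.DataFrame, cpi: CpiSeries) -> pd.DataFrame:
    """Convert all monetary fields to the CPI reference year's prices.

    Each amount is multiplied by ``cpi[reference_year] / cpi[wave_year]``;
    within-record ratios (hence all CHE flags) are unchanged. A wave year
    absent from the series is a hard error.
    """
    years = records["wave_year"].unique()
    missing = [int(y) for y in years if int(y) not in cpi.index]
    if missing:
        raise KeyError(
            "CPI series has no index value for year(s): "
            + ", ".join(str(y) for y in sorted(missing))
        )
    df = records.copy()
    factors = df["wave_year"].map(lambda y: cpi.factor(int(y)))
    for col in MONETARY_FIELDS:
        df[col] = df[col] * factors
    return df


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a harmonized table as CSV with canonical column names."""
    records.to_csv(path, index=False)


def write_report(report, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
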