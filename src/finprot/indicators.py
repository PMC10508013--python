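"""Catastrophic health expenditure (CHE) and medical impoverishment (MI) flags.

Two families of household-level indicators:

* CHE: out-of-pocket (OOP) health spending at or above a threshold share of a
  denominator — either total consumption or nonfood "capacity to pay"
  (consumption minus food). The comparator is ``>=`` ("at least").
* MI: a household above a poverty line on gross per-capita consumption that
  falls strictly below it once OOP spending is subtracted. Its weighted share
  equals the net-minus-gross poverty headcount difference.

Edge rules, stated once here and relied on throughout:

* capacity to pay may be nonpositive (food over-reporting); then CHE is true
  iff OOP > 0. OOP of exactly 0 is never CHE under any definition.
* poverty uses a strict ``<`` comparator (on the line is not poor); negative
  net consumption is poor.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import weighted_median

#: Constants of the canonical six-definition set.
DEFAULT_PPP_FACTOR = 3.52
DEFAULT_CPI_FACTOR = 1.13
DAYS_PER_YEAR = 365
DEFAULT_MEDIAN_SHARE = 0.60

#: Grouping columns carried from the household table into the flag table
#: when present.
GROUPING_FIELDS = (
    "survey_id",
    "wave_year",
    "urban",
    "province",
    "weight",
    "income_quartile",
)


@dataclasses.dataclass(frozen=True)
class CheDefinition:
    """One CHE definition: a threshold share of a spending denominator."""

    denominator: str  # "nonfood_capacity" or "total_consumption"
    threshold: float

    _DENOMINATORS = ("nonfood_capacity", "total_consumption")

    def __post_init__(self) -> None:
        if self.denominator not in self._DENOMINATORS:
            raise ValueError(
                f"denominator must be one of {self._DENOMINATORS}, "
                f"got {self.denominator!r}"
            )
        if not 0 < self.threshold < 1:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")

    @property
    def label(self) -> str:
        stem = "nonfood" if self.denominator == "nonfood_capacity" else "total"
        return f"che_{stem}_{round(self.threshold * 100):d}"


@dataclasses.dataclass(frozen=True)
class PovertyLine:
    """A poverty line in currency units per person per *year*.

    ``provenance`` keeps the construction inputs: for an absolute line the
    (base USD/day, PPP factor, CPI factor, days/year) tuple plus the per-day
    value; for a relative line the median share used.
    """

    kind: str  # "absolute" or "relative"
    value: float
    label: str
    provenance: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"kind must be 'absolute' or 'relative', got {self.kind!r}")
        if not self.value > 0:
            raise ValueError(f"poverty line value must be positive, got {self.value}")


def capacity_to_pay(record: Mapping) -> float:
    """Nonfood spending capacity: total consumption minus food expenditure.

    May be nonpositive when food was reported above total consumption; such
    values are passed through untouched (the CHE classifier handles them).
    """
    return float(record["consumption_total"]) - float(record["food_expenditure"])


def classify_che(record: Mapping, definition: CheDefinition) -> bool:
    """True iff OOP health spending is at least ``threshold`` x denominator."""
    oop = float(record["oop_health_expenditure"])
    if definition.denominator == "nonfood_capacity":
        denom = capacity_to_pay(record)
    else:
        denom = float(record["consumption_total"])
    if denom <= 0:
        return oop > 0
    return oop >= definition.threshold * denom


def absolute_poverty_line(
    base_usd_per_day: float,
    ppp_factor: float = DEFAULT_PPP_FACTOR,
    cpi_factor: float = DEFAULT_CPI_FACTOR,
    days_per_year: int = DAYS_PER_YEAR,
    label: str | None = None,
) -> PovertyLine:
    """Convert a USD-per-person-day line to local currency per person-year.

    Per-day value = base x PPP x CPI; annual value = per-day x days_per_year.
    """
    for name, v in (
        ("base_usd_per_day", base_usd_per_day),
        ("ppp_factor", ppp_factor),
        ("cpi_factor", cpi_factor),
        ("days_per_year", days_per_year),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    per_day = base_usd_per_day * ppp_factor * cpi_factor
    if label is None:
        label = f"abs_{base_usd_per_day:g}usd"
    return PovertyLine(
        kind="absolute",
        value=per_day * days_per_year,
        label=label,
        provenance={
            "base_usd_per_day": base_usd_per_day,
            "ppp_factor": ppp_factor,
            "cpi_factor": cpi_factor,
            "days_per_year": days_per_year,
            "value_per_day": per_day,
        },
    )


def relative_poverty_line(
    records: pd.DataFrame,
    median_share: float = DEFAULT_MEDIAN_SHARE,
    label: str = "relative",
) -> PovertyLine:
    """Share of the survey-weighted median per-capita consumption.

    The median is taken over households with their survey weights (lower
    weighted-median convention at ties).
    """
    if len(records) == 0:
        raise ValueError("cannot compute a relative poverty line on an empty table")
    pc = records["consumption_total"] / records["family_size"]
    med = weighted_median(pc.to_numpy(), records["weight"].to_numpy())
    return PovertyLine(
        kind="relative",
        value=median_share * med,
        label=label,
        provenance={"median_share": median_share, "weighted_median_pc": med},
    )


def classify_poor(record: Mapping, line: PovertyLine, net_of_oop: bool) -> bool:
    """Per-capita consumption strictly below the line, gross or net of OOP."""
    cons = float(record["consumption_total"])
    if net_of_oop:
        cons -= float(record["oop_health_expenditure"])
    return cons / float(record["family_size"]) < line.value


def classify_mi(record: Mapping, line: PovertyLine) -> bool:
    """Medically impoverished: not poor on gross consumption, poor net of OOP."""
    return not classify_poor(record, line, net_of_oop=False) and classify_poor(
        record, line, net_of_oop=True
    )


def canonical_che_definitions() -> list[CheDefinition]:
    """The three standard CHE definitions (40% nonfood, 10% and 25% total)."""
    return [
        CheDefinition("nonfood_capacity", 0.40),
        CheDefinition("total_consumption", 0.10),
        CheDefinition("total_consumption", 0.25),
    ]


def canonical_poverty_lines(records: pd.DataFrame) -> list[PovertyLine]:
    """The three standard poverty lines (1.9 and 3.1 USD absolute, 60% median).

    The relative line is computed from ``records``, so lines are per-table.
    """
    return [
        absolute_poverty_line(1.9),
        absolute_poverty_line(3.1),
        relative_poverty_line(records),
    ]


def build_flag_table(
    records: pd.DataFrame,
    che_definitions: Sequence[CheDefinition] = (),
    poverty_lines: Sequence[PovertyLine] = (),
) -> pd.DataFrame:
    """Vectorized indicator flags for every household.

    One row per household: ``household_id``, any grouping columns present in
    ``records`` (survey, wave, urban, province, weight, quartile), one boolean
    column per CHE definition, and ``poor_gross_*`` / ``poor_net_*`` / ``mi_*``
    per poverty line. Equivalent to applying the scalar classifiers row by
    row (property-tested against that loop).
    """
    carried = ["household_id"] + [c for c in GROUPING_FIELDS if c in records.columns]
    out = records[carried].copy()

    cons = records["consumption_total"].to_numpy(dtype=float)
    food = records["food_expenditure"].to_numpy(dtype=float)
    oop = records["oop_health_expenditure"].to_numpy(dtype=float)
    size = records["family_size"].to_numpy(dtype=float)

    for d in che_definitions:
        denom = cons - food if d.denominator == "nonfood_capacity" else cons
        flags = np.where(denom <= 0, oop > 0, oop >= d.threshold * denom)
        out[d.label] = flags.astype(bool)

    gross_pc = cons / size
    net_pc = (cons - oop) / size
    for line in poverty_lines:
        poor_gross = gross_pc < line.value
        poor_net = net_pc < line.value
        out[f"poor_gross_{line.label}"] = poor_gross
        out[f"poor_net_{line.label}"] = poor_net
        out[f"mi_{line.label}"] = ~poor_gross & poor_net
    return out


def indicator_columns(flag_table: pd.DataFrame) -> list[str]:
    """Names of the CHE/MI indicator columns in a flag table."""
    return [
        c for c in flag_table.columns if c.startswith("che_") or c.startswith("mi_")
    ]
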