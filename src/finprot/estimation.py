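"""Survey-weighted incidence, quartile assignment, subgroup gaps, and trends.

All estimates use the cross-sectional survey weights only (no strata/PSU
design information). Standard errors of weighted proportions use the
sum-of-squared-normalized-weights (Kish-style) formula; confidence intervals
are normal-approximation 95% intervals truncated to [0, 100].
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import weighted_quantile

Z_95 = 1.96

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclasses.dataclass(frozen=True)
class IncidenceEstimate:
    """A weighted proportion in percent, with its 95% confidence interval."""

    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    n: int
    weighted_n: float

    def __str__(self) -> str:  # "14.95 (14.23-15.68)" layout
        return f"{self.estimate:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"


@dataclasses.dataclass(frozen=True)
class GapEstimate:
    """Subgroup incidences plus a reference contrast and a chi-square test."""

    group_estimates: Mapping[str, IncidenceEstimate]
    contrast: tuple[str, str]
    gap_pp: float
    chi2_stat: float
    df: int
    p_value: float

    @property
    def stars(self) -> str:
        if self.p_value < 0.01:
            return "***"
        if self.p_value < 0.05:
            return "**"
        if self.p_value < 0.10:
            return "*"
        return ""


def weighted_incidence(flags, weights) -> IncidenceEstimate:
    """Weighted share of true flags, in percent, with a Kish-style SE.

    p = sum(w*f)/sum(w); SE = sqrt(p(1-p) * sum(w^2)/sum(w)^2). With equal
    weights this reduces to the simple binomial proportion and its SRS
    standard error.
    """
    f = np.asarray(flags, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.size == 0:
        raise ValueError("weighted_incidence of an empty sequence")
    if f.shape != w.shape:
        raise ValueError("flags and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wsum = w.sum()
    p = float((w * f).sum() / wsum)
    se = float(np.sqrt(p * (1.0 - p) * (w**2).sum() / wsum**2))
    est, se_pct = 100.0 * p, 100.0 * se
    return IncidenceEstimate(
        estimate=est,
        std_error=se_pct,
        ci_low=max(0.0, est - Z_95 * se_pct),
        ci_high=min(100.0, est + Z_95 * se_pct),
        n=int(f.size),
        weighted_n=float(wsum),
    )


def assign_income_quartiles(records: pd.DataFrame) -> pd.Series:
    """Quartile labels Q1..Q4 by per-capita household income.

    Cut points are weighted quantiles at 25/50/75% (lower convention);
    assignment is lower-closed, so a household exactly on a cut point shares
    the lower group. With degenerate cut points (identical incomes) everyone
    lands in Q1.
    """
    if len(records) == 0:
        raise ValueError("cannot assign quartiles on an empty table")
    pc = (records["income_total"] / records["family_size"]).to_numpy(dtype=float)
    w = records["weight"].to_numpy(dtype=float)
    cuts = [weighted_quantile(pc, w, q) for q in (0.25, 0.50, 0.75)]
    idx = np.searchsorted(np.asarray(cuts), pc, side="left")
    # searchsorted 'left' puts values equal to a cut point at that cut's index,
    # i.e. into the lower group
    labels = np.asarray(QUARTILE_LABELS)[idx]
    return pd.Series(labels, index=records.index, name="income_quartile")


def _pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a G x 2 table; zero-expected cells contribute 0."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    df = table.shape[0] - 1
    return stat, df, float(stats.chi2.sf(stat, df))


def subgroup_gap(
    flag_table: pd.DataFrame,
    indicator: str,
    grouping: str,
    contrast: tuple[str, str],
) -> GapEstimate:
    """Per-group weighted incidences, their contrast, and a chi-square test.

    ``gap_pp`` is group a minus group b of ``contrast`` in percentage points.
    The chi-square is Pearson's statistic on the G x 2 table of weighted
    counts with weights rescaled so they sum to the unweighted sample size
    (first-order scale correction only; no design-effect adjustment).
    """
    if grouping not in flag_table.columns:
        raise KeyError(f"grouping column {grouping!r} not in flag table")
    if indicator not in flag_table.columns:
        raise KeyError(f"indicator column {indicator!r} not in flag table")

    groups = {}
    counts = []
    w_all = flag_table["weight"].to_numpy(dtype=float)
    scale = len(flag_table) / w_all.sum()
    for label, sub in flag_table.groupby(grouping, sort=True, observed=True):
        f = sub[indicator].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        groups[label] = weighted_incidence(f, w)
        ws = w * scale
        counts.append([(ws * f).sum(), (ws * (1.0 - f)).sum()])

    for g in contrast:
        if g not in groups:
            raise ValueError(f"contrast group {g!r} is empty or absent")

    stat, df, p = _pearson_chi2(np.asarray(counts))
    gap = groups[contrast[0]].estimate - groups[contrast[1]].estimate
    return GapEstimate(
        group_estimates=groups,
        contrast=tuple(contrast),
        gap_pp=gap,
        chi2_stat=stat,
        df=df,
        p_value=p,
    )


def trend_series(
    tables: Sequence[tuple[int, pd.DataFrame]],
    indicator: str,
) -> list[tuple[int, IncidenceEstimate]]:
    """Weighted incidence of one indicator per wave, sorted by year."""
    if len(tables) == 0:
        raise ValueError("trend_series requires at least one wave")
    years = [y for y, _ in tables]
    if len(set(years)) != len(years):
        dupes = sorted({y for y in years if years.count(y) > 1})
        raise ValueError(f"duplicate wave year(s): {dupes}")
    out = []
    for year, table in sorted(tables, key=lambda t: t[0]):
        est = weighted_incidence(
            table[indicator].to_numpy(dtype=float),
            table["weight"].to_numpy(dtype=float),
        )
        out.append((year, est))
    return out
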