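"""End-to-end pipeline: load -> validate -> rebase -> flag -> estimate ->
regress -> report.

Driven by a :class:`RunConfig` (YAML-friendly). Each stage's failure is
re-raised as a :class:`PipelineError` naming the stage; a JSON manifest
reconciles row counts across stages and records the config hash and seed so
identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import estimation, indicators, io, regression, synthetic

DEFAULT_REGRESSION_OUTCOMES = ("che_nonfood_40", "mi_abs_1.9usd")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``synthetic`` (generator parameters) or ``inputs``
    (list of ``{path, dialect}`` file pairs) must be given.
    """

    synthetic: dict | None = None
    inputs: Sequence[dict] | None = None
    cpi: dict | None = None  # {"index": {year: value}, "reference_year": year}
    che_definitions: Sequence[dict] | None = None
    poverty_lines: Sequence[dict] | None = None
    groupings: Sequence[str] = ("residence", "income_quartile")
    regression_outcomes: Sequence[str] = DEFAULT_REGRESSION_OUTCOMES
    output_dir: str = "finprot_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be set")
        if self.che_definitions is not None and self.poverty_lines is not None:
            if len(self.che_definitions) == 0 and len(self.poverty_lines) == 0:
                raise ValueError("definition set must be nonempty")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groupings"] = list(self.groupings)
        d["regression_outcomes"] = list(self.regression_outcomes)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _build_definitions(config: RunConfig) -> list[indicators.CheDefinition]:
    if config.che_definitions is None:
        return indicators.canonical_che_definitions()
    return [
        indicators.CheDefinition(d["denominator"], float(d["threshold"]))
        for d in config.che_definitions
    ]


def _build_lines(config: RunConfig, records: pd.DataFrame) -> list[indicators.PovertyLine]:
    if config.poverty_lines is None:
        return indicators.canonical_poverty_lines(records)
    lines = []
    for spec in config.poverty_lines:
        if spec["kind"] == "absolute":
            lines.append(
                indicators.absolute_poverty_line(
                    float(spec["base_usd_per_day"]),
                    float(spec.get("ppp_factor", indicators.DEFAULT_PPP_FACTOR)),
                    float(spec.get("cpi_factor", indicators.DEFAULT_CPI_FACTOR)),
                    int(spec.get("days_per_year", indicators.DAYS_PER_YEAR)),
                    label=spec.get("label"),
                )
            )
        elif spec["kind"] == "relative":
            lines.append(
                indicators.relative_poverty_line(
                    records,
                    float(spec.get("median_share", indicators.DEFAULT_MEDIAN_SHARE)),
                    label=spec.get("label", "relative"),
                )
            )
        else:
            raise ValueError(f"unknown poverty line kind {spec['kind']!r}")
    return lines


def _stars(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def _format_incidence_text(table: pd.DataFrame) -> str:
    lines = []
    for (survey, year), sub in table.groupby(["survey_id", "wave_year"]):
        lines.append(f"== {survey} {year} ==")
        for _, row in sub.iterrows():
            lines.append(
                f"  {row['indicator']:<22s} "
                f"{row['estimate']:.2f} ({row['ci_low']:.2f}-{row['ci_high']:.2f})"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``): config hash,
    seed, and per-stage row counts. Outputs under ``output_dir``:
    ``households.csv``, ``flags.csv``, ``incidence.csv``/``.txt``,
    ``gaps.csv``/``.txt``, ``trend.csv`` (multi-wave runs),
    ``regression.csv``/``.txt``, ``validation.json``, ``load.json``.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "counts": {},
    }

    # ---- load -------------------------------------------------------------
    try:
        load_reports = []
        if config.synthetic is not None:
            syn = synthetic.SyntheticConfig(**{**config.synthetic, "seed": config.seed})
            records = synthetic.generate_households(syn)
            load_reports.append(
                {"survey_id": syn.survey_id, "n_source_rows": len(records),
                 "n_dropped_missing": 0, "n_loaded": len(records)}
            )
        else:
            parts = []
            for item in config.inputs:
                dialect = io.DialectMap.from_file(item["dialect"])
                part, rep = io.load_survey(item["path"], dialect)
                parts.append(part)
                load_reports.append(rep.to_dict())
            records = pd.concat(parts, ignore_index=True)
        manifest["counts"]["loaded"] = len(records)
        manifest["counts"]["dropped_missing"] = sum(
            r["n_dropped_missing"] for r in load_reports
        )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError("load", str(e)) from e

    # ---- validate ---------------------------------------------------------
    try:
        records, vreport = io.validate_records(records)
        manifest["counts"]["valid"] = vreport.n_valid
        manifest["counts"]["dropped_validation"] = vreport.n_input - vreport.n_valid
    except Exception as e:  # noqa: BLE001
        raise PipelineError("validate", str(e)) from e

    # ---- rebase -----------------------------------------------------------
    if config.cpi is not None:
        try:
            cpi = io.CpiSeries(
                index={int(k): float(v) for k, v in config.cpi["index"].items()},
                reference_year=int(config.cpi["reference_year"]),
            )
            records = io.rebase_currency(records, cpi)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("rebase", str(e)) from e

    # ---- flags (per survey x wave; relative lines and quartiles are local) -
    try:
        che_defs = _build_definitions(config)
        flag_parts = []
        for (_, _), sub in records.groupby(["survey_id", "wave_year"], sort=True):
            sub = sub.copy()
            sub["income_quartile"] = estimation.assign_income_quartiles(sub)
            lines = _build_lines(config, sub)
            flag_parts.append(indicators.build_flag_table(sub, che_defs, lines))
        flags = pd.concat(flag_parts, ignore_index=True)
        flags["residence"] = flags["urban"].map({1: "urban", 0: "rural"})
        manifest["counts"]["flagged"] = len(flags)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("flags", str(e)) from e

    indicator_cols = indicators.indicator_columns(flags)

    # ---- incidence --------------------------------------------------------
    try:
        rows = []
        for (survey, year), sub in flags.groupby(["survey_id", "wave_year"]):
            for col in indicator_cols:
                est = estimation.weighted_incidence(
                    sub[col].to_numpy(float), sub["weight"].to_numpy(float)
                )
                rows.append(
                    {"survey_id": survey, "wave_year": year, "indicator": col,
                     "estimate": est.estimate, "std_error": est.std_error,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "n": est.n, "weighted_n": est.weighted_n}
                )
        incidence = pd.DataFrame(rows)
        incidence.to_csv(out / "incidence.csv", index=False)
        (out / "incidence.txt").write_text(_format_incidence_text(incidence))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("incidence", str(e)) from e

    # ---- gaps -------------------------------------------------------------
    try:
        contrasts = {"residence": ("rural", "urban"), "income_quartile": ("Q1", "Q4")}
        rows, text = [], []
        for grouping in config.groupings:
            contrast = contrasts.get(grouping)
            if contrast is None:
                raise ValueError(f"no contrast defined for grouping {grouping!r}")
            for (survey, year), sub in flags.groupby(["survey_id", "wave_year"]):
                for col in indicator_cols:
                    gap = estimation.subgroup_gap(sub, col, grouping, contrast)
                    for label, est in gap.group_estimates.items():
                        rows.append(
                            {"survey_id": survey, "wave_year": year,
                             "indicator": col, "grouping": grouping,
                             "group": label, "estimate": est.estimate,
                             "ci_low": est.ci_low, "ci_high": est.ci_high,
                             "gap_pp": gap.gap_pp, "chi2": gap.chi2_stat,
                             "df": gap.df, "p_value": gap.p_value}
                        )
                    text.append(
                        f"{survey} {year} {col} [{grouping}] "
                        f"{contrast[0]}-{contrast[1]} gap: "
                        f"{gap.gap_pp:.2f}pp{_stars(gap.p_value)} "
                        f"(chi2={gap.chi2_stat:.2f}, df={gap.df})"
                    )
        pd.DataFrame(rows).to_csv(out / "gaps.csv", index=False)
        (out / "gaps.txt").write_text("\n".join(text) + "\n")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("gaps", str(e)) from e

    # ---- trend (only meaningful with several waves) -----------------------
    try:
        trend_rows = []
        for survey, sub in flags.groupby("survey_id"):
            waves = [(int(y), t) for y, t in sub.groupby("wave_year")]
            if len(waves) < 2:
                continue
            for col in indicator_cols:
                for year, est in estimation.trend_series(waves, col):
                    trend_rows.append(
                        {"survey_id": survey, "wave_year": year, "indicator": col,
                         "estimate": est.estimate, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "n": est.n}
                    )
        if trend_rows:
            pd.DataFrame(trend_rows).to_csv(out / "trend.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("trend", str(e)) from e

    # ---- regression -------------------------------------------------------
    try:
        reg_rows, reg_text = [], []
        full = flags.merge(
            records[["household_id", "consumption_total", "food_expenditure",
                     "income_total", "family_size"]],
            on="household_id",
        )
        for (survey, year), sub in full.groupby(["survey_id", "wave_year"]):
            for outcome in config.regression_outcomes:
                if outcome not in sub.columns:
                    continue
                try:
                    X, y, w, _ = regression.build_design(sub, outcome)
                    fit = regression.fit_probit(X, y, w)
                except ValueError as err:
                    reg_text.append(f"{survey} {year} {outcome}: not estimable ({err})")
                    continue
                reg_text.append(f"== {survey} {year} {outcome} (n={fit.n_used}) ==")
                for name, row in fit.ame.iterrows():
                    reg_rows.append(
                        {"survey_id": survey, "wave_year": year, "outcome": outcome,
                         "covariate": name, "ame": row["ame"],
                         "robust_se": row["robust_se"], "p_value": row["p_value"],
                         "n": fit.n_used}
                    )
                    reg_text.append(
                        f"  {name:<20s} {row['ame']:+.4f}{_stars(row['p_value']):<3s} "
                        f"({row['robust_se']:.4f})"
                    )
        if reg_rows:
            pd.DataFrame(reg_rows).to_csv(out / "regression.csv", index=False)
            (out / "regression.txt").write_text("\n".join(reg_text) + "\n")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("regression", str(e)) from e

    # ---- bundle -----------------------------------------------------------
    io.write_table(records, out / "households.csv")
    flags.to_csv(out / "flags.csv", index=False)
    io.write_report(vreport, out / "validation.json")
    with open(out / "load.json", "w") as fh:
        json.dump(load_reports, fh, indent=2)
    manifest["counts"]["input_reconciled"] = (
        manifest["counts"]["loaded"] + manifest["counts"]["dropped_missing"]
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
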