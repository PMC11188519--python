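"""File schemas, validated readers/writers and pipeline configuration.

All tables are comma-separated UTF-8 text with a header row; dates are
ISO-8601 (``YYYY-MM-DD``); intervals are half-open.  Readers validate the
header against the documented schema (missing columns abort), parse dates,
and collect row-level failures (bad dates, unknown categories) into a
rejects table with reasons instead of aborting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import (
    ADMIN_END,
    CARE_TYPES,
    DEFAULT_COVARIATES,
    HISTORICAL_END,
    HISTORICAL_START,
    MATCH_VARS,
    MATCHING_RATIO,
    MIN_REGISTRATION_DAYS,
    OUTCOME_WINDOW_DAYS,
    STUDY_START,
)
from .outcomes import UnitCostTable

__all__ = [
    "PipelineConfig",
    "read_patients",
    "read_events",
    "read_unit_costs",
    "read_inputs",
    "write_table",
    "write_unit_costs",
]

PATIENT_DATE_COLUMNS = (
    "registration_start",
    "registration_end",
    "death_date",
    "longcovid_diagnosis_date",
    "longcovid_resolved_date",
)
PATIENT_BOOL_COLUMNS = (
    "asthma",
    "mental_health",
    "prior_covid_hospitalisation",
    "positive_test_before_index",
)
PATIENT_REQUIRED = (
    "patient_id",
    "age",
    "sex",
    "region",
    "ethnicity",
    "imd_quintile",
    "bmi_category",
    "n_comorbidities",
    "n_vaccine_doses_at_index",
) + PATIENT_BOOL_COLUMNS + PATIENT_DATE_COLUMNS

EVENT_REQUIRED = ("patient_id", "date", "care_type", "code", "cost")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing required column(s): {missing}")


def _parse_bool(s: pd.Series) -> pd.Series:
    return s.astype(str).str.lower().isin(("true", "1", "yes"))


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "patient_id": str,
            "imd_quintile": str,
            "n_vaccine_doses_at_index": str,
        },
    )
    _require_columns(df, PATIENT_REQUIRED, "patient")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id(s): {dups[:10]}")
    for c in PATIENT_DATE_COLUMNS:
        df[c] = pd.to_datetime(df[c], format="ISO8601", errors="coerce")
    for c in PATIENT_BOOL_COLUMNS:
        df[c] = _parse_bool(df[c])
    if "practice_coding" in df.columns:
        df["practice_coding"] = _parse_bool(df["practice_coding"])
    return df


def read_events(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (valid events, rejects-with-reason)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    _require_columns(df, EVENT_REQUIRED, "event")
    df["code"] = df["code"].fillna("")
    reasons = pd.Series("", index=df.index)
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    reasons[dates.isna()] = "bad date"
    bad_type = ~df["care_type"].isin(CARE_TYPES)
    reasons[bad_type & (reasons == "")] = "unknown care_type"
    cost = pd.to_numeric(df["cost"], errors="coerce")
    bad_cost = df["cost"].notna() & cost.isna()
    reasons[bad_cost & (reasons == "")] = "bad cost"
    rejects = df[reasons != ""].assign(reason=reasons[reasons != ""])
    ok = df[reasons == ""].copy()
    ok["date"] = dates[reasons == ""]
    ok["cost"] = cost[reasons == ""]
    if "end_date" in ok.columns:
        ok["end_date"] = pd.to_datetime(ok["end_date"], errors="coerce")
    else:
        ok["end_date"] = pd.NaT
    return ok.reset_index(drop=True), rejects.reset_index(drop=True)


def read_unit_costs(path) -> UnitCostTable:
    df = pd.read_csv(path, dtype={"item": str})
    _require_columns(df, ("item", "cost"), "unit-cost")
    gp = df.loc[df["item"] == "gp_consultation", "cost"]
    chapters = {
        row["item"].removeprefix("bnf_"): float(row["cost"])
        for _, row in df.iterrows()
        if row["item"].startswith("bnf_")
    }
    return UnitCostTable(
        gp_consultation_cost=float(gp.iloc[0]) if len(gp) else 41.0,
        bnf_chapter_costs=chapters,
    )


def write_unit_costs(unit_costs: UnitCostTable, path) -> None:
    rows = [("gp_consultation", unit_costs.gp_consultation_cost)]
    rows += [(f"bnf_{ch}", c) for ch, c in sorted(unit_costs.bnf_chapter_costs.items())]
    pd.DataFrame(rows, columns=["item", "cost"]).to_csv(path, index=False)


def read_inputs(paths: dict):
    """Read and validate the three input tables.

    ``paths`` maps ``patients``/``events``/``unit_costs`` to file paths.
    Returns (patients, events, unit_costs, event rejects).
    """
    patients = read_patients(paths["patients"])
    events, rejects = read_events(paths["events"])
    unit_costs = read_unit_costs(paths["unit_costs"])
    return patients, events, unit_costs, rejects


def write_table(df: pd.DataFrame, path) -> None:
    """CSV writer with ISO dates; round-trips through the paired reader."""
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Study constants, modelling options and file locations for one run."""

    study_start: str = str(STUDY_START.date())
    admin_end: str = str(ADMIN_END.date())
    historical_start: str = str(HISTORICAL_START.date())
    historical_end: str = str(HISTORICAL_END.date())
    matching_ratio: int = MATCHING_RATIO
    match_vars: tuple = MATCH_VARS
    outcome_window_days: int = OUTCOME_WINDOW_DAYS
    min_registration_days: int = MIN_REGISTRATION_DAYS
    covariates: tuple = DEFAULT_COVARIATES
    outcomes: tuple = ("total_visits", "total_cost")
    dispersion_threshold: float = 1.0
    bootstrap_reps: int = 0  # 0 disables bootstrap CIs
    seed: int = 0
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationParams overrides
    run_did: bool = True
    run_descriptives: bool = True
    stratify_by: tuple = ()
    patients_path: str | None = None
    events_path: str | None = None
    unit_costs_path: str | None = None
    output_dir: str = "careuse_output"

    def __post_init__(self):
        if self.matching_ratio < 1:
            raise ValueError("matching_ratio must be >= 1")
        if 0 < self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be 0 or >= 100 for reported CIs")
        order = [
            pd.Timestamp(self.historical_start),
            pd.Timestamp(self.historical_end),
            pd.Timestamp(self.study_start),
            pd.Timestamp(self.admin_end),
        ]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError("config dates must be ordered: historical < study < end")
        if not self.simulate and not (
            self.patients_path and self.events_path and self.unit_costs_path
        ):
            raise ValueError("non-simulated runs need all three input paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for k in ("match_vars", "covariates", "outcomes", "stratify_by"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
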