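"""Turn event streams into person-period analysis rows.

Visit counting deduplicates within care type by calendar date: several
prescriptions issued on one day count as a single visit, but a GP visit and
an A&E attendance on the same day count separately.  Hospital admissions
count only when the stay exceeds one day (discharge date after admission
date).  Costs are assembled from unit costs for GP consultations (flat
tariff per deduplicated visit) and prescriptions (raw prescription frequency
times the BNF-chapter unit cost — deliberately *not* deduplicated), and from
recorded per-event costs for secondary care.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    CARE_TYPES,
    COSTED_CARE_TYPES,
    GP_CONSULTATION_COST,
    HISTORICAL_END,
    HISTORICAL_START,
    age_category,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UnitCostTable",
    "count_utilisation",
    "assemble_costs",
    "build_analysis_rows",
]

#: stable column order of the analysis-row table (the modelling contract)
ANALYSIS_ROW_COLUMNS = [
    "patient_id",
    "set_id",
    "group",
    "period",
    "follow_up_days",
    "n_gp",
    "n_prescription",
    "n_ae",
    "n_admission",
    "n_outpatient",
    "total_visits",
    "cost_gp",
    "cost_prescription",
    "cost_ae",
    "cost_admission",
    "cost_outpatient",
    "total_cost",
    "cost_missing_flag",
    "age",
    "age_category",
    "sex",
    "region",
    "ethnicity",
    "imd_quintile",
    "asthma",
    "mental_health",
    "comorbidity_level",
    "prior_covid_hospitalisation",
    "n_vaccine_doses_at_index",
]


@dataclass(frozen=True)
class UnitCostTable:
    """Unit costs: a flat GP consultation tariff and per-chapter drug costs."""

    gp_consultation_cost: float = GP_CONSULTATION_COST
    bnf_chapter_costs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.gp_consultation_cost < 0:
            raise ValueError("gp_consultation_cost must be >= 0")
        for ch, c in self.bnf_chapter_costs.items():
            if c < 0:
                raise ValueError(f"negative unit cost for BNF chapter {ch!r}")


def _in_interval(events: pd.DataFrame, interval) -> pd.Series:
    start, end = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
    if end <= start:
        raise ValueError("interval must be a non-empty half-open date range")
    d = pd.to_datetime(events["date"])
    return (d >= start) & (d < end)


def _countable(events: pd.DataFrame) -> pd.DataFrame:
    """Drop admission records that did not span more than one day."""
    if "end_date" not in events.columns or events.empty:
        return events
    adm = events["care_type"] == "admission"
    same_day = adm & ~(pd.to_datetime(events["end_date"]) > pd.to_datetime(events["date"]))
    return events[~same_day]


def count_utilisation(events: pd.DataFrame, interval) -> dict:
    """Per-care-type counts of distinct event dates inside ``interval``."""
    sel = events[_in_interval(events, interval)] if len(events) else events
    sel = _countable(sel)
    counts = {}
    for t in CARE_TYPES:
        sub = sel[sel["care_type"] == t]
        counts[t] = int(sub["date"].nunique())
    return counts


def assemble_costs(
    events: pd.DataFrame,
    counts: dict,
    unit_costs: UnitCostTable,
    interval,
) -> dict:
    """Cost components for one person-period.

    GP cost is the deduplicated visit count times the consultation tariff;
    prescription cost is the *raw* prescription frequency per BNF chapter
    times the chapter unit cost; secondary-care costs are sums of recorded
    event costs.  Rows with any missing secondary cost are flagged.
    """
    sel = events[_in_interval(events, interval)] if len(events) else events
    if len(sel) and (pd.to_numeric(sel["cost"], errors="coerce") < 0).any():
        raise ValueError("negative recorded event cost")
    out = {"cost_gp": counts["gp"] * unit_costs.gp_consultation_cost}
    rx = sel[sel["care_type"] == "prescription"]
    chapter_counts = rx["code"].value_counts()
    missing_chapters = sorted(
        set(chapter_counts.index) - set(unit_costs.bnf_chapter_costs)
    )
    if missing_chapters:
        raise ValueError(
            f"unit-cost table missing BNF chapters: {missing_chapters}"
        )
    out["cost_prescription"] = float(
        sum(
            n * unit_costs.bnf_chapter_costs[ch]
            for ch, n in chapter_counts.items()
        )
    )
    any_missing = False
    for t in COSTED_CARE_TYPES:
        sub = sel[sel["care_type"] == t]
        costs = pd.to_numeric(sub["cost"], errors="coerce")
        any_missing = any_missing or bool(costs.isna().any())
        out[f"cost_{t}"] = float(costs.sum())
    out["total_cost"] = float(sum(out[k] for k in out))
    out["cost_missing_flag"] = any_missing
    return out


# ---------------------------------------------------------------------------
# vectorised table construction


def _count_table(events: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated counts per interval row.

    ``intervals`` has ``row_id``/``patient_id``/``start``/``end``; a patient
    may carry several (disjoint) intervals, e.g. a pre-diagnosis comparator
    spell and their own exposed follow-up, and each interval row is counted
    over its own window.
    """
    ev = events.merge(
        intervals[["row_id", "patient_id", "start", "end"]],
        on="patient_id",
        how="inner",
    )
    d = pd.to_datetime(ev["date"])
    ev = ev[(d >= ev["start"]) & (d < ev["end"])]
    ev = _countable(ev)
    dedup = ev.drop_duplicates(["row_id", "care_type", "date"])
    counts = (
        dedup.groupby(["row_id", "care_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    for t in CARE_TYPES:
        if t not in counts.columns:
            counts[t] = 0
    counts = counts[list(CARE_TYPES)].rename(columns={t: f"n_{t}" for t in CARE_TYPES})
    return counts.reindex(intervals["row_id"], fill_value=0)


def _cost_table(
    events: pd.DataFrame, intervals: pd.DataFrame, unit_costs: UnitCostTable
) -> pd.DataFrame:
    ev = events.merge(
        intervals[["row_id", "patient_id", "start", "end"]],
        on="patient_id",
        how="inner",
    )
    d = pd.to_datetime(ev["date"])
    ev = ev[(d >= ev["start"]) & (d < ev["end"])]
    if len(ev) and (pd.to_numeric(ev["cost"], errors="coerce") < 0).any():
        raise ValueError("negative recorded event cost")
    rids = intervals["row_id"]
    out = pd.DataFrame(index=pd.Index(rids, name="row_id"))

    rx = ev[ev["care_type"] == "prescription"]
    chapters = set(rx["code"].unique()) - set(unit_costs.bnf_chapter_costs)
    if chapters:
        raise ValueError(f"unit-cost table missing BNF chapters: {sorted(chapters)}")
    rx_cost = (
        rx.assign(c=rx["code"].map(unit_costs.bnf_chapter_costs))
        .groupby("row_id")["c"]
        .sum()
    )
    out["cost_prescription"] = rx_cost.reindex(rids, fill_value=0.0).fillna(0.0)

    any_missing = pd.Series(False, index=out.index)
    for t in COSTED_CARE_TYPES:
        sub = ev[ev["care_type"] == t]
        costs = pd.to_numeric(sub["cost"], errors="coerce")
        out[f"cost_{t}"] = (
            costs.groupby(sub["row_id"]).sum().reindex(rids, fill_value=0.0)
        )
        miss = costs.isna().groupby(sub["row_id"]).any()
        any_missing |= miss.reindex(rids, fill_value=False)
    out["cost_missing_flag"] = any_missing
    return out


_COMORBIDITY_LEVELS = {0: "0", 1: "1", 2: "2"}


def _covariate_frame(patients: pd.DataFrame) -> pd.DataFrame:
    cov = patients.set_index("patient_id")[
        [
            "age",
            "sex",
            "region",
            "ethnicity",
            "imd_quintile",
            "asthma",
            "mental_health",
            "n_comorbidities",
            "prior_covid_hospitalisation",
            "n_vaccine_doses_at_index",
        ]
    ].copy()
    cov["age_category"] = age_category(cov["age"].to_numpy()).to_numpy()
    cov["comorbidity_level"] = (
        cov.pop("n_comorbidities").map(lambda k: _COMORBIDITY_LEVELS.get(k, "3+"))
    )
    for col in ("ethnicity", "imd_quintile"):
        cov[col] = cov[col].fillna("missing").replace("", "missing")
    return cov


def build_analysis_rows(
    matched_sets: pd.DataFrame,
    follow_ups: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    unit_costs: UnitCostTable,
    period: str,
) -> pd.DataFrame:
    """One analysis row per matched-set member for the requested period.

    Contemporary rows use each member's censored follow-up interval;
    historical rows use the fixed pre-pandemic window (possibly truncated by
    death or deregistration) and require registration from before that
    window's start.  Zero-length intervals are excluded with a logged count.
    """
    members = follow_ups[["patient_id", "set_id", "group", "index_date"]].copy()
    missing = set(members["patient_id"]) - set(patients["patient_id"])
    if missing:
        raise ValueError(
            f"patients in matched sets but absent from patient table: "
            f"{sorted(missing)[:10]}"
        )
    pat = patients.set_index("patient_id")
    if period == "contemporary":
        members["start"] = pd.to_datetime(follow_ups["index_date"].values)
        members["end"] = pd.to_datetime(follow_ups["end"].values)
    elif period == "historical":
        reg_start = pat["registration_start"].reindex(members["patient_id"]).values
        ok = pd.to_datetime(reg_start) <= HISTORICAL_START
        members = members[np.asarray(ok)]
        members["start"] = HISTORICAL_START
        stop = pd.concat(
            [
                pat["registration_end"].reindex(members["patient_id"]).reset_index(drop=True),
                pat["death_date"].reindex(members["patient_id"]).reset_index(drop=True),
            ],
            axis=1,
        ).min(axis=1, skipna=True)
        members["end"] = np.minimum(
            pd.to_datetime(stop.fillna(HISTORICAL_END)).values,
            np.datetime64(HISTORICAL_END),
        )
    else:
        raise ValueError(f"unknown period {period!r}")

    members["follow_up_days"] = (
        pd.to_datetime(members["end"]) - pd.to_datetime(members["start"])
    ).dt.days
    zero_len = members["follow_up_days"] <= 0
    if zero_len.any():
        logger.info(
            "excluding %d zero-length %s intervals", int(zero_len.sum()), period
        )
        members = members[~zero_len]

    # a patient can appear in several member rows (as both exposed and a
    # pre-diagnosis comparator); count each row over its own interval
    members = members.reset_index(drop=True)
    members["row_id"] = members.index
    intervals = members[["row_id", "patient_id", "start", "end"]]
    counts = _count_table(events, intervals)
    costs = _cost_table(events, intervals, unit_costs)
    cov = _covariate_frame(patients)

    rows = members.merge(counts, left_on="row_id", right_index=True, how="left")
    rows = rows.merge(costs, left_on="row_id", right_index=True, how="left")
    rows = rows.merge(cov, left_on="patient_id", right_index=True, how="left")
    ncols = [f"n_{t}" for t in CARE_TYPES]
    rows[ncols] = rows[ncols].fillna(0).astype(int)
    rows["total_visits"] = rows[ncols].sum(axis=1)
    rows["cost_gp"] = rows["n_gp"] * unit_costs.gp_consultation_cost
    cost_cols = [f"cost_{t}" for t in CARE_TYPES]
    rows[cost_cols] = rows[cost_cols].fillna(0.0)
    rows["total_cost"] = rows[cost_cols].sum(axis=1)
    rows["cost_missing_flag"] = rows["cost_missing_flag"].fillna(False).astype(bool)
    rows["period"] = period
    return rows[ANALYSIS_ROW_COLUMNS].reset_index(drop=True)
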