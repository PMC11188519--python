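"""Eligibility, 1:5 exact matching, index dates and censored follow-up.

Exposed patients (those with a long COVID diagnosis) are matched without
replacement to up to five comparators sharing exact integer age, sex and
region, processed in ascending index-date order with seeded tie-breaking.
A person diagnosed later may serve as a comparator before their diagnosis
(they are then censored at diagnosis) and still head their own matched set.
All intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    ADMIN_END,
    MATCH_VARS,
    MATCHING_RATIO,
    MIN_REGISTRATION_DAYS,
    OUTCOME_WINDOW_DAYS,
    STUDY_START,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedSet",
    "FollowUpInterval",
    "apply_eligibility",
    "match_exposed",
    "compute_follow_up",
    "compute_follow_up_table",
]


@dataclass(frozen=True)
class MatchedSet:
    exposed_id: str
    comparator_ids: tuple
    index_date: pd.Timestamp

    def __post_init__(self):
        if not 1 <= len(self.comparator_ids) <= 5:
            raise ValueError("a matched set has 1-5 comparators")


@dataclass(frozen=True)
class FollowUpInterval:
    start: pd.Timestamp
    end: pd.Timestamp
    end_reason: str

    @property
    def days(self) -> int:
        return (self.end - self.start).days

    @property
    def zero_length(self) -> bool:
        return self.end <= self.start


def apply_eligibility(
    patients: pd.DataFrame,
    study_start: pd.Timestamp = STUDY_START,
    min_registration_days: int = MIN_REGISTRATION_DAYS,
    require_coding_practice: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Apply cohort entry rules; returns (eligible, exclusion tally).

    Retains adults (18+ at ``study_start``) registered continuously from at
    least ``min_registration_days`` before ``study_start`` through
    ``study_start`` itself.  Patients with missing registration dates are
    excluded with reason ``incomplete_record`` rather than aborting.
    """
    study_start = pd.Timestamp(study_start)
    tally: dict[str, int] = {}
    df = patients.copy()

    incomplete = (
        df["registration_start"].isna() | df["registration_end"].isna()
    )
    tally["incomplete_record"] = int(incomplete.sum())
    df = df[~incomplete]

    under_age = df["age"] < 18
    tally["age"] = int(under_age.sum())
    df = df[~under_age]

    cutoff = study_start - pd.Timedelta(days=min_registration_days)
    unregistered = (pd.to_datetime(df["registration_start"]) > cutoff) | (
        pd.to_datetime(df["registration_end"]) < study_start
    )
    tally["registration"] = int(unregistered.sum())
    df = df[~unregistered]

    if require_coding_practice and "practice_coding" in df.columns:
        non_coding = ~df["practice_coding"].astype(bool)
        tally["non_coding_practice"] = int(non_coding.sum())
        df = df[~non_coding]

    logger.info("eligibility exclusions: %s", tally)
    return df.reset_index(drop=True), tally


def match_exposed(
    eligible: pd.DataFrame,
    ratio: int = MATCHING_RATIO,
    match_vars: tuple = MATCH_VARS,
    seed: int = 0,
) -> pd.DataFrame:
    """1:``ratio`` exact matching without replacement.

    Returns a long table (set_id, exposed_id, comparator_id, index_date),
    one row per comparator.  Exposed people are processed in ascending
    index-date order (ties broken by patient id); candidates must share the
    match-variable values, be registered and alive at the index date, be
    undiagnosed before it, and not already be used in another set.  Exposed
    with no available comparator are dropped with a logged count.
    """
    if ratio < 1:
        raise ValueError("matching ratio must be >= 1")
    df = eligible.reset_index(drop=True)
    diag = pd.to_datetime(df["longcovid_diagnosis_date"])
    exposed = df[diag.notna()].copy()
    exposed["index_date"] = pd.to_datetime(exposed["longcovid_diagnosis_date"])
    exposed = exposed.sort_values(
        ["index_date", "patient_id"], kind="mergesort"
    )

    # per-stratum candidate arrays for fast repeated filtering
    key = list(match_vars)
    strata: dict = {}
    for stratum, sub in df.groupby(key, observed=True, sort=False):
        strata[stratum] = {
            "ids": sub["patient_id"].to_numpy(),
            "diag": pd.to_datetime(sub["longcovid_diagnosis_date"]).to_numpy(),
            "reg_start": pd.to_datetime(sub["registration_start"]).to_numpy(),
            "reg_end": pd.to_datetime(sub["registration_end"]).to_numpy(),
            "death": pd.to_datetime(sub["death_date"]).to_numpy(),
            "used": np.zeros(len(sub), dtype=bool),
        }

    rng = np.random.default_rng(seed)
    records = []
    unmatched = 0
    set_id = 0
    for _, person in exposed.iterrows():
        stratum = tuple(person[k] for k in key)
        if len(key) == 1:
            stratum = stratum[0]
        pool = strata.get(stratum)
        if pool is None:
            unmatched += 1
            continue
        index_date = np.datetime64(person["index_date"])
        ok = (
            ~pool["used"]
            & (pool["ids"] != person["patient_id"])
            & (np.isnat(pool["diag"]) | (pool["diag"] > index_date))
            & (pool["reg_start"] <= index_date)
            & (pool["reg_end"] >= index_date)
            & (np.isnat(pool["death"]) | (pool["death"] > index_date))
        )
        candidates = np.flatnonzero(ok)
        if candidates.size == 0:
            unmatched += 1
            continue
        take = min(ratio, candidates.size)
        chosen = rng.choice(candidates, size=take, replace=False)
        pool["used"][chosen] = True
        for cid in pool["ids"][np.sort(chosen)]:
            records.append(
                (f"s{set_id:06d}", person["patient_id"], cid, person["index_date"])
            )
        set_id += 1

    if unmatched:
        logger.info("dropped %d exposed with no available comparator", unmatched)
    out = pd.DataFrame(
        records, columns=["set_id", "exposed_id", "comparator_id", "index_date"]
    )
    out["index_date"] = pd.to_datetime(out["index_date"])
    out.attrs["n_unmatched_exposed"] = unmatched
    return out


# censoring reasons in tie-break precedence order
_REASON_PRECEDENCE = (
    "death",
    "deregistration",
    "resolved_code",
    "comparator_diagnosed",
    "admin_end",
    "window_end",
)


def compute_follow_up(
    patient: pd.Series,
    index_date,
    group: str,
    window_days: int = OUTCOME_WINDOW_DAYS,
    admin_end=ADMIN_END,
) -> FollowUpInterval:
    """Censored follow-up from the index date.

    End is the earliest of death, deregistration, a resolved-code date
    (exposed), the comparator's own later diagnosis (comparator), the
    administrative end, and ``index_date + window_days``; the reason is the
    argmin (ties broken by the precedence above).  A zero-length interval
    (e.g. death on the index date) is returned flagged, for exclusion from
    modelling rather than an abort.
    """
    if group not in ("exposed", "comparator"):
        raise ValueError(f"unknown group {group!r}")
    index_date = pd.Timestamp(index_date)
    candidates = {
        "death": pd.to_datetime(patient.get("death_date")),
        "deregistration": pd.to_datetime(patient.get("registration_end")),
        "admin_end": pd.Timestamp(admin_end),
        "window_end": index_date + pd.Timedelta(days=window_days),
    }
    if group == "exposed":
        candidates["resolved_code"] = pd.to_datetime(
            patient.get("longcovid_resolved_date")
        )
    else:
        candidates["comparator_diagnosed"] = pd.to_datetime(
            patient.get("longcovid_diagnosis_date")
        )
    end, reason = None, None
    for r in _REASON_PRECEDENCE:
        d = candidates.get(r)
        if d is None or pd.isna(d):
            continue
        if end is None or d < end:
            end, reason = d, r
    return FollowUpInterval(start=index_date, end=end, end_reason=reason)


def compute_follow_up_table(
    matched_sets: pd.DataFrame,
    patients: pd.DataFrame,
    window_days: int = OUTCOME_WINDOW_DAYS,
    admin_end=ADMIN_END,
) -> pd.DataFrame:
    """Vectorised follow-up for every matched-set member.

    Returns one row per member: patient_id, set_id, group, index_date, end,
    end_reason, follow_up_days, zero_length.
    """
    exp = matched_sets.drop_duplicates("set_id")[["set_id", "exposed_id", "index_date"]]
    exp = exp.rename(columns={"exposed_id": "patient_id"})
    exp["group"] = "exposed"
    comp = matched_sets[["set_id", "comparator_id", "index_date"]].rename(
        columns={"comparator_id": "patient_id"}
    )
    comp["group"] = "comparator"
    members = pd.concat([exp, comp], ignore_index=True)

    pat = patients.set_index("patient_id")
    idx = members["patient_id"]
    index_date = pd.to_datetime(members["index_date"])
    cand = pd.DataFrame(
        {
            "death": pd.to_datetime(pat["death_date"]).reindex(idx).values,
            "deregistration": pd.to_datetime(pat["registration_end"])
            .reindex(idx)
            .values,
            "resolved_code": pd.to_datetime(pat["longcovid_resolved_date"])
            .reindex(idx)
            .values,
            "comparator_diagnosed": pd.to_datetime(pat["longcovid_diagnosis_date"])
            .reindex(idx)
            .values,
            "admin_end": pd.Timestamp(admin_end),
            "window_end": (index_date + pd.Timedelta(days=window_days)).values,
        }
    )
    is_exposed = (members["group"] == "exposed").to_numpy()
    cand.loc[is_exposed, "comparator_diagnosed"] = pd.NaT
    cand.loc[~is_exposed, "resolved_code"] = pd.NaT

    ordered = cand[list(_REASON_PRECEDENCE)]
    end = ordered.min(axis=1, skipna=True)
    out = members.copy()
    out["index_date"] = index_date.values
    out["end"] = pd.to_datetime(end).values
    out["end_reason"] = _tie_break_reasons(ordered, out["end"])
    out["follow_up_days"] = (out["end"] - out["index_date"]).dt.days
    out["zero_length"] = out["follow_up_days"] <= 0
    return out


def _tie_break_reasons(ordered: pd.DataFrame, end: pd.Series) -> np.ndarray:
    """First column (in precedence order) equal to the minimum date."""
    arr = ordered.to_numpy(dtype="datetime64[ns]")
    end_arr = end.to_numpy(dtype="datetime64[ns]")
    hit = arr == end_arr[:, None]
    first = hit.argmax(axis=1)
    return np.asarray(list(_REASON_PRECEDENCE), dtype=object)[first]
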