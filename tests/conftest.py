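"""Shared fixtures: a small simulated cohort run once per session, plus
helpers for constructing hand-checked event streams."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from careuse.cohort import apply_eligibility, compute_follow_up_table, match_exposed
from careuse.outcomes import build_analysis_rows
from careuse.synthetic import (
    SimulationParams,
    default_unit_costs,
    generate_events,
    generate_population,
)


def make_patient(
    patient_id="p1",
    age=45,
    sex="Female",
    region="London",
    diagnosis=None,
    resolved=None,
    death=None,
    reg_start="2015-01-01",
    reg_end="2023-06-30",
    **extra,
) -> dict:
    base = {
        "patient_id": patient_id,
        "age": age,
        "sex": sex,
        "region": region,
        "ethnicity": "White",
        "imd_quintile": "3",
        "bmi_category": "Normal weight",
        "asthma": False,
        "mental_health": False,
        "n_comorbidities": 0,
        "prior_covid_hospitalisation": False,
        "n_vaccine_doses_at_index": "2",
        "positive_test_before_index": False,
        "registration_start": pd.Timestamp(reg_start),
        "registration_end": pd.Timestamp(reg_end),
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "longcovid_diagnosis_date": pd.Timestamp(diagnosis) if diagnosis else pd.NaT,
        "longcovid_resolved_date": pd.Timestamp(resolved) if resolved else pd.NaT,
        "practice_id": "pr001",
        "practice_coding": True,
    }
    base.update(extra)
    return base


def make_events(records) -> pd.DataFrame:
    """Events from (patient_id, date, care_type[, code, cost, end_date])."""
    if not records:
        empty = pd.DataFrame(
            columns=["patient_id", "date", "care_type", "code", "cost", "end_date"]
        )
        empty["date"] = pd.to_datetime(empty["date"])
        empty["end_date"] = pd.to_datetime(empty["end_date"])
        return empty
    rows = []
    for r in records:
        pid, date, care_type = r[0], r[1], r[2]
        code = r[3] if len(r) > 3 else ""
        cost = r[4] if len(r) > 4 else np.nan
        end = r[5] if len(r) > 5 else None
        rows.append(
            {
                "patient_id": pid,
                "date": pd.Timestamp(date),
                "care_type": care_type,
                "code": code,
                "cost": cost,
                "end_date": pd.Timestamp(end) if end else pd.NaT,
            }
        )
    return pd.DataFrame(rows)


def build_cohort_rows(params: SimulationParams, match_seed: int = 0, event_seed: int = 1):
    """Run generation -> matching -> follow-up -> events -> analysis rows."""
    patients, truth = generate_population(params)
    eligible, _ = apply_eligibility(patients)
    matched = match_exposed(eligible, seed=match_seed)
    follow_ups = compute_follow_up_table(matched, patients)
    usable = follow_ups[~follow_ups["zero_length"]]
    windows = usable.rename(columns={"index_date": "start"})[
        ["patient_id", "group", "start", "end"]
    ].copy()
    windows["exposed"] = windows.pop("group") == "exposed"
    events = generate_events(
        patients, windows, params, "contemporary",
        rng=np.random.default_rng(event_seed),
    )
    rows = build_analysis_rows(
        matched, usable, events, patients, default_unit_costs(), "contemporary"
    )
    return {
        "patients": patients,
        "truth": truth,
        "matched": matched,
        "follow_ups": usable,
        "events": events,
        "rows": rows,
    }


@pytest.fixture(scope="session")
def cohort():
    """Moderate simulated cohort shared across model tests."""
    return build_cohort_rows(SimulationParams(n_exposed=800, seed=3))


@pytest.fixture(scope="session")
def unit_costs():
    return default_unit_costs()
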