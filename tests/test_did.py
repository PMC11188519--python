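"""Difference-in-difference rows, estimates and common-trend checks."""

import numpy as np
import pandas as pd
import pytest

from careuse.cohort import compute_follow_up_table
from careuse.did import _did_from_means, build_did_rows, check_common_trend, fit_did
from careuse.outcomes import build_analysis_rows
from careuse.predict import bootstrap_ci
from careuse.synthetic import (
    SimulationParams,
    default_unit_costs,
    generate_events,
    generate_population,
)

from conftest import make_events, make_patient

COSTS = default_unit_costs()


def _mini_cohort():
    patients = pd.DataFrame(
        [make_patient("e1", diagnosis="2021-01-01")]
        + [make_patient(f"c{i}") for i in range(3)]
    )
    matched = pd.DataFrame(
        {
            "set_id": "s0",
            "exposed_id": "e1",
            "comparator_id": [f"c{i}" for i in range(3)],
            "index_date": pd.Timestamp("2021-01-01"),
        }
    )
    return patients, matched


def test_two_rows_per_person_with_both_periods():
    patients, matched = _mini_cohort()
    ev = make_events(
        [("e1", "2019-06-01", "gp"), ("e1", "2021-06-01", "gp"),
         ("c0", "2019-08-01", "gp")]
    )
    rows = build_did_rows(matched, ev, patients, COSTS)
    per_person = rows.groupby("patient_id").size()
    assert (per_person == 2).all()
    e1 = rows[rows["patient_id"] == "e1"].set_index("period")
    assert e1.loc["historical", "n_gp"] == 1
    assert e1.loc["contemporary", "n_gp"] == 1


def test_late_registration_excluded_from_did():
    patients, matched = _mini_cohort()
    patients.loc[patients["patient_id"] == "c0", "registration_start"] = pd.Timestamp(
        "2020-06-01"
    )
    rows = build_did_rows(matched, make_events([("e1", "2019-06-01", "gp")]),
                          patients, COSTS)
    assert "c0" not in set(rows["patient_id"])


def test_historical_window_filter_by_hand():
    patients, matched = _mini_cohort()
    ev = make_events(
        [
            ("e1", "2019-02-28", "gp"),  # before the window
            ("e1", "2019-03-01", "gp"),  # first day in
            ("e1", "2020-02-29", "gp"),  # last day in
            ("e1", "2020-03-01", "gp"),  # out (half-open)
        ]
    )
    rows = build_did_rows(matched, ev, patients, COSTS)
    hist = rows[(rows["patient_id"] == "e1") & (rows["period"] == "historical")]
    assert int(hist["n_gp"].iloc[0]) == 2


def _did_rows_from_generator(params, seed=0, did_multiplier=None):
    patients, truth = generate_population(params)
    from careuse.cohort import apply_eligibility, match_exposed

    eligible, _ = apply_eligibility(patients)
    matched = match_exposed(eligible, seed=seed)
    fu = compute_follow_up_table(matched, patients)
    usable = fu[~fu["zero_length"]]
    windows = usable.rename(columns={"index_date": "start"})[
        ["patient_id", "group", "start", "end"]
    ].copy()
    windows["exposed"] = windows.pop("group") == "exposed"
    rng = np.random.default_rng(seed + 1)
    ev_cont = generate_events(patients, windows, params, "contemporary", rng)
    hist_ok = patients.loc[
        patients["registration_start"] <= pd.Timestamp("2019-03-01"), "patient_id"
    ]
    members = usable.drop_duplicates("patient_id")
    members = members[members["patient_id"].isin(set(hist_ok))]
    hist_windows = pd.DataFrame(
        {
            "patient_id": members["patient_id"],
            "start": pd.Timestamp("2019-03-01"),
            "end": pd.Timestamp("2020-03-01"),
        }
    )
    ev_hist = generate_events(patients, hist_windows, params, "historical", rng)
    events = pd.concat([ev_hist, ev_cont], ignore_index=True)
    rows = build_did_rows(matched, events, patients, COSTS, follow_ups=usable)
    return rows, truth


NULL = dict(
    p_nonzero_exposed=0.8,
    p_nonzero_comparator=0.8,
    rate_ratio_true=1.0,
    did_effect_true=0.0,
    cost_ratio_true=1.0,
    covariate_effect_map={},
)


def test_null_did_estimate_near_zero():
    rows, _ = _did_rows_from_generator(
        SimulationParams(n_exposed=400, seed=61, **NULL), seed=2
    )
    res = fit_did(rows, covariates=())

    def refit(sample):
        return fit_did(sample, covariates=()).did_estimate

    lo, hi = bootstrap_ci(refit, rows, n_reps=40, seed=3)
    se = (hi - lo) / (2 * 1.96)
    assert abs(res.did_estimate) < 3 * se


def test_did_recovers_generator_effect():
    params = SimulationParams(
        n_exposed=500, seed=71, did_effect_true=np.log(1.45),
        covariate_effect_map={},
    )
    rows, truth = _did_rows_from_generator(params, seed=4)
    res = fit_did(rows, covariates=())
    implied = truth.implied_estimands(
        patient_ids=rows["patient_id"].unique()
    )

    def refit(sample):
        return fit_did(sample, covariates=()).did_estimate

    lo, hi = bootstrap_ci(refit, rows, n_reps=40, seed=5)
    se = (hi - lo) / (2 * 1.96)
    assert abs(res.did_estimate - implied["did_true"]) < 3 * se
    # the part-2 interaction coefficient targets the DID log-rate shift
    coef, coef_se = res.interaction_part2
    assert abs(coef - np.log(1.45)) < 3 * coef_se


def test_period_swap_flips_sign():
    rows, _ = _did_rows_from_generator(
        SimulationParams(n_exposed=250, seed=81), seed=6
    )
    res = fit_did(rows, covariates=())
    swapped = rows.assign(
        period=rows["period"].map(
            {"historical": "contemporary", "contemporary": "historical"}
        )
    )
    res_sw = fit_did(swapped, covariates=())
    assert res_sw.did_estimate == pytest.approx(
        -res.did_estimate, rel=1e-3, abs=1e-3
    )


def test_contrast_equals_four_mean_recomputation():
    rows, _ = _did_rows_from_generator(
        SimulationParams(n_exposed=150, seed=91), seed=7
    )
    res = fit_did(rows, covariates=())
    m = res.predicted_means
    brute = (
        m[("exposed", "contemporary")] - m[("exposed", "historical")]
    ) - (m[("comparator", "contemporary")] - m[("comparator", "historical")])
    assert res.did_estimate == brute  # exact identity, no tolerance
    assert _did_from_means(m)["did"] == brute


def test_empty_cell_raises():
    rows, _ = _did_rows_from_generator(
        SimulationParams(n_exposed=100, seed=95), seed=8
    )
    with pytest.raises(ValueError, match="cell"):
        fit_did(rows[~((rows.group == "exposed") & (rows.period == "historical"))],
                covariates=())


def test_common_shift_identical_groups_gives_null_did():
    """A calendar-wide rate shift is differenced away when the groups are
    exchangeable (no group effect)."""
    params = SimulationParams(n_exposed=500, seed=55, **NULL)
    shifted = params.with_(did_effect_true=0.0, base_rate=params.base_rate * 1.4)
    patients, _ = generate_population(params)
    from careuse.cohort import apply_eligibility, match_exposed

    eligible, _ = apply_eligibility(patients)
    matched = match_exposed(eligible, seed=9)
    fu = compute_follow_up_table(matched, patients)
    usable = fu[~fu["zero_length"]]
    windows = usable.rename(columns={"index_date": "start"})[
        ["patient_id", "group", "start", "end"]
    ].copy()
    windows["exposed"] = windows.pop("group") == "exposed"
    rng = np.random.default_rng(10)
    # contemporary rates carry a +40% secular shift common to both groups
    ev_cont = generate_events(patients, windows, shifted, "contemporary", rng)
    members = usable.drop_duplicates("patient_id").merge(
        patients[["patient_id", "registration_start"]], on="patient_id"
    )
    members = members[members["registration_start"] <= pd.Timestamp("2019-03-01")]
    hist_windows = pd.DataFrame(
        {
            "patient_id": members["patient_id"],
            "start": pd.Timestamp("2019-03-01"),
            "end": pd.Timestamp("2020-03-01"),
        }
    )
    ev_hist = generate_events(patients, hist_windows, params, "historical", rng)
    rows = build_did_rows(
        matched, pd.concat([ev_hist, ev_cont]), patients, COSTS, follow_ups=usable
    )
    res = fit_did(rows, covariates=())

    def refit(sample):
        return fit_did(sample, covariates=()).did_estimate

    lo, hi = bootstrap_ci(refit, rows, n_reps=40, seed=11)
    se = (hi - lo) / (2 * 1.96)
    assert abs(res.did_estimate) < 3 * se


def test_common_trend_table_bookkeeping(cohort):
    patients = cohort["patients"]
    members = cohort["follow_ups"].drop_duplicates("patient_id")[
        ["patient_id", "group"]
    ].merge(patients, on="patient_id")
    hist = generate_events(
        patients,
        pd.DataFrame(
            {
                "patient_id": members["patient_id"],
                "start": pd.Timestamp("2019-03-01"),
                "end": pd.Timestamp("2020-03-01"),
            }
        ),
        SimulationParams(n_exposed=800, seed=3),
        "historical",
        np.random.default_rng(12),
    )
    table = check_common_trend(hist, members, bins=4)
    assert len(table) == 8  # 4 bins x 2 groups
    assert table["zero_person_time"].sum() == 0
    # parallel generated trends: per-bin gaps stay near their mean
    gaps = table.drop_duplicates("bin")["gap"]
    assert (gaps - gaps.mean()).abs().max() < 0.25 * gaps.mean()


def test_common_trend_single_group():
    members = pd.DataFrame([make_patient(f"x{i}") for i in range(5)])
    members["group"] = "comparator"
    ev = make_events([(f"x{i}", "2019-06-01", "gp") for i in range(5)])
    table = check_common_trend(ev, members, bins=3)
    assert len(table) == 3
    assert table["gap"].isna().all()
    assert table["rate"].notna().all()
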