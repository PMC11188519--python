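"""Baseline tables, cost imputation, stratified effects and restrictions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from careuse.descriptives import (
    apply_restriction,
    column_percentages,
    impute_missing_costs,
    stratified_analysis,
    table_one,
)
from careuse.synthetic import _sample_ztnb
from careuse.twopart import ModelSpec, fit_binomial_part, fit_truncated_count_part

from conftest import make_events, make_patient


def test_percentages_recompute_from_counts():
    pct = column_percentages({"Yes": 4655, "No": 48333})
    assert pct == {"Yes": 8.8, "No": 91.2}


def test_chi_square_without_continuity_correction():
    # 2x2 table (20, 80; 10, 90): sum (O-E)^2/E = 3.92 by hand
    chi2, _, _, _ = stats.chi2_contingency(
        [[20, 80], [10, 90]], correction=False
    )
    assert chi2 == pytest.approx(3.92, abs=0.005)


def _members(n=120, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append(
            make_patient(
                f"p{i}",
                age=int(rng.integers(20, 80)),
                sex=rng.choice(["Female", "Male"]),
                asthma=bool(rng.random() < 0.2),
            )
        )
    df = pd.DataFrame(rows)
    df["group"] = np.where(np.arange(n) % 6 == 0, "exposed", "comparator")
    return df


def test_table_one_structure_and_percentage_identity():
    members = _members()
    tab = table_one(members)
    sex = tab[tab["factor"] == "sex"]
    for col, ncol, total in (
        ("exposed_pct", "exposed_n", (members["group"] == "exposed").sum()),
        ("comparator_pct", "comparator_n", (members["group"] == "comparator").sum()),
    ):
        recomputed = (100.0 * sex[ncol] / total).round(1)
        assert (sex[col] == recomputed).all()
    assert "age" in set(tab["factor"])  # continuous row with t-test


def test_identical_distributions_give_p_one():
    members = _members()
    members["sex"] = "Female"
    members.loc[members.index[:40], "sex"] = "Male"
    # make sex independent of group by construction: same proportions
    members["sex"] = np.tile(["Male", "Female", "Female"], 40)
    tab = table_one(members, factors=("sex",), continuous=())
    # single-level factor: p not applicable
    members2 = members.assign(region="London")
    tab2 = table_one(members2, factors=("region",), continuous=())
    assert tab2["p_value"].isna().all()
    assert (tab["p_value"] <= 1.0).all()


def test_imputation_fills_mean_and_preserves_observed():
    ev = make_events(
        [
            ("a", "2021-01-01", "ae", "", 100.0),
            ("b", "2021-01-02", "ae", "", 300.0),
            ("c", "2021-01-03", "ae", "", np.nan),
            ("d", "2021-01-04", "gp"),
        ]
    )
    out, tally = impute_missing_costs(ev)
    assert tally == {"ae": 1, "admission": 0, "outpatient": 0}
    assert out.loc[2, "cost"] == 200.0
    assert out.loc[0, "cost"] == 100.0 and out.loc[1, "cost"] == 300.0
    assert np.isnan(out.loc[3, "cost"])  # GP rows are unit-costed, untouched
    obs_mean_before = ev[ev.care_type == "ae"]["cost"].mean()
    obs_mean_after = out[out.care_type == "ae"]["cost"].mean()
    assert obs_mean_after == pytest.approx(obs_mean_before)


def test_imputation_noop_without_missing():
    ev = make_events([("a", "2021-01-01", "ae", "", 50.0)])
    out, tally = impute_missing_costs(ev)
    pd.testing.assert_frame_equal(out, ev)
    assert sum(tally.values()) == 0


def test_imputation_all_missing_raises():
    ev = make_events([("a", "2021-01-01", "outpatient", "", np.nan)])
    with pytest.raises(ValueError, match="outpatient"):
        impute_missing_costs(ev)


def _stratified_rows(n, rr_a, rr_b, seed, alpha=0.5, p_any=0.8):
    rng = np.random.default_rng(seed)
    g = rng.random(n) < 0.4
    s = rng.random(n) < 0.5
    mu = 10.0 * np.where(s, np.where(g, rr_b, 1.0), np.where(g, rr_a, 1.0))
    y = np.zeros(n, dtype=int)
    pos = rng.random(n) < p_any
    y[pos] = _sample_ztnb(rng, mu[pos], alpha)
    return pd.DataFrame(
        {
            "total_visits": y,
            "group": np.where(g, "exposed", "comparator"),
            "sex": np.where(s, "Male", "Female"),
            "follow_up_days": 365,
        }
    )


def test_stratified_estimates_and_power():
    rows = _stratified_rows(20_000, rr_a=2.0, rr_b=1.0, seed=13)
    spec = ModelSpec("total_visits", covariates=("sex",))
    out = stratified_analysis(rows, spec, "sex")
    assert [s.level for s in out] == ["Female", "Male"]
    assert out[0].lrt_df == 1
    by = {s.level: s for s in out}
    assert by["Female"].rr_ci[0] < 2.0 < by["Female"].rr_ci[1]
    assert by["Male"].rr_ci[0] < 1.0 < by["Male"].rr_ci[1]
    assert out[0].lrt_p_part2 < 0.01


def test_null_interaction_lrt_calibration():
    """Without effect modification the LRT rarely rejects at 5%."""
    rejections = 0
    n_reps = 20
    spec = ModelSpec("total_visits", covariates=("sex",),
                     family_override="negbin")
    for i in range(n_reps):
        rows = _stratified_rows(1500, rr_a=1.5, rr_b=1.5, seed=200 + i)
        out = stratified_analysis(rows, spec, "sex")
        if out[0].lrt_p_part2 < 0.05:
            rejections += 1
    assert rejections <= 0.2 * n_reps


def test_saturated_interaction_equals_separate_fits():
    rows = _stratified_rows(4000, rr_a=1.8, rr_b=1.2, seed=17)
    spec = ModelSpec("total_visits", covariates=("sex",),
                     family_override="poisson")
    out = {s.level: s for s in stratified_analysis(rows, spec, "sex")}
    for level in ("Female", "Male"):
        sub = rows[rows["sex"] == level]
        spec0 = ModelSpec("total_visits", covariates=(),
                          family_override="poisson")
        p1 = fit_binomial_part(sub, spec0)
        p2 = fit_truncated_count_part(sub, spec0, family="poisson")
        assert out[level].odds_ratio == pytest.approx(
            float(np.exp(p1.params["group_exposed"])), rel=1e-5
        )
        assert out[level].rate_ratio == pytest.approx(
            float(np.exp(p2.params["group_exposed"])), rel=1e-4
        )


def test_stratify_variable_must_be_adjusted_for():
    rows = _stratified_rows(500, 1.0, 1.0, seed=1)
    with pytest.raises(ValueError, match="covariates"):
        stratified_analysis(rows, ModelSpec("total_visits", covariates=()), "sex")


def test_empty_cell_raises():
    rows = _stratified_rows(500, 1.0, 1.0, seed=2)
    rows = rows[~((rows.group == "exposed") & (rows.sex == "Male"))]
    with pytest.raises(ValueError, match="cell"):
        stratified_analysis(
            rows, ModelSpec("total_visits", covariates=("sex",)), "sex"
        )


def test_restriction_positive_test_filter():
    patients = pd.DataFrame(
        [make_patient(f"p{i}", positive_test_before_index=(i < 4)) for i in range(10)]
    )
    kept, _, tally = apply_restriction(patients, make_events([]),
                                       "positive_test_before_index")
    assert len(kept) == 4
    assert tally["excluded_patients"] == 6


def test_restriction_prior_gp_consult():
    patients = pd.DataFrame([make_patient("a"), make_patient("b")])
    ev = make_events(
        [("a", "2020-01-15", "gp"), ("b", "2019-10-15", "gp")]
    )  # only a's visit falls in Nov 2019 - Nov 2020
    kept, _, _ = apply_restriction(patients, ev, "prior_gp_consult_within_1y")
    assert list(kept["patient_id"]) == ["a"]


def test_restriction_drop_first_gp_event():
    patients = pd.DataFrame([make_patient("a", diagnosis="2021-01-01")])
    ev = make_events([("a", "2021-03-01", "gp")])
    index_dates = pd.Series(
        {"a": pd.Timestamp("2021-01-01")}
    )
    _, out, tally = apply_restriction(patients, ev, "drop_first_gp_event",
                                      index_dates=index_dates)
    assert tally["dropped_events"] == 1
    assert len(out) == 0  # the only post-index GP visit is removed


def test_unknown_restriction_lists_valid_rules():
    patients = pd.DataFrame([make_patient("a")])
    with pytest.raises(ValueError, match="prior_gp_consult_within_1y"):
        apply_restriction(patients, make_events([]), "left_handed_only")
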