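"""The two-part model: logistic part, family selection, truncated count
part, Gamma cost part, and their invariances."""

import numpy as np
import pandas as pd
import pytest

from careuse.synthetic import _sample_ztnb
from careuse.twopart import (
    ModelSpec,
    fit_binomial_part,
    fit_gamma_cost_part,
    fit_truncated_count_part,
    fit_two_part,
    overdispersion_check,
)

SPEC0 = ModelSpec(outcome="total_visits", covariates=())


def _rows(outcome, group, follow_up_days=365, **cov):
    df = pd.DataFrame({"total_visits": outcome, "group": group})
    df["follow_up_days"] = follow_up_days
    for k, v in cov.items():
        df[k] = v
    return df


def test_two_by_two_odds_ratio_closed_form():
    rows = _rows(
        np.r_[np.repeat(1, 80), np.repeat(0, 20), np.repeat(1, 50), np.repeat(0, 50)],
        np.r_[np.repeat("exposed", 100), np.repeat("comparator", 100)],
    )
    fit = fit_binomial_part(rows, SPEC0)
    or_, lo, hi = (
        float(np.exp(fit.params["group_exposed"])),
        *map(float, np.exp(fit.conf_int().loc["group_exposed"])),
    )
    assert or_ == pytest.approx(4.0, rel=1e-6)
    assert lo < 4.0 < hi


def test_null_odds_ratio_is_one():
    rows = _rows(
        np.r_[np.repeat(1, 70), np.repeat(0, 30), np.repeat(1, 70), np.repeat(0, 30)],
        np.r_[np.repeat("exposed", 100), np.repeat("comparator", 100)],
    )
    fit = fit_binomial_part(rows, SPEC0)
    assert np.exp(fit.params["group_exposed"]) == pytest.approx(1.0, abs=1e-8)


def test_logistic_recovery_of_group_log_odds():
    rng = np.random.default_rng(6)
    n = 20_000
    g = np.r_[np.repeat("exposed", n // 2), np.repeat("comparator", n // 2)]
    eta = np.where(g == "exposed", 1.0, -1.0)  # log-odds difference 2.0
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    fit = fit_binomial_part(_rows(y, g), SPEC0)
    err = abs(fit.params["group_exposed"] - 2.0)
    assert err < 3 * fit.bse["group_exposed"]


def test_constant_outcome_raises():
    rows = _rows(np.repeat(1, 50), np.repeat(["exposed", "comparator"], 25))
    with pytest.raises(ValueError, match="constant"):
        fit_binomial_part(rows, SPEC0)


def test_perfect_separation_detected():
    rows = _rows(
        np.r_[np.repeat(1, 50), np.repeat(0, 50)],
        np.r_[np.repeat("exposed", 50), np.repeat("comparator", 50)],
    )
    with pytest.raises(ValueError, match="separation"):
        fit_binomial_part(rows, SPEC0)


def test_overdispersion_ratio_near_one_for_poisson_data():
    rng = np.random.default_rng(4)
    y = rng.poisson(5.0, 5000)
    rows = _rows(y, rng.choice(["exposed", "comparator"], 5000))
    ratio, family = overdispersion_check(rows, SPEC0)
    assert 0.9 < ratio < 1.1
    assert family == ("negbin" if ratio > 1.0 else "poisson")


def test_overdispersed_data_selects_negbin():
    rng = np.random.default_rng(4)
    mu, alpha = 5.0, 1.0
    y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu), 5000)
    rows = _rows(y, rng.choice(["exposed", "comparator"], 5000))
    ratio, family = overdispersion_check(rows, SPEC0)
    assert ratio > 1.5
    assert family == "negbin"

    spec_hi = ModelSpec(outcome="total_visits", covariates=(),
                        dispersion_threshold=ratio + 1)
    _, family_hi = overdispersion_check(rows, spec_hi)
    assert family_hi == "poisson"

    spec_override = ModelSpec(outcome="total_visits", covariates=(),
                              family_override="poisson")
    _, family_o = overdispersion_check(rows, spec_override)
    assert family_o == "poisson"


def _ztnb_rows(n, rr, alpha, seed, mu0=14.0, p_any=1.0):
    rng = np.random.default_rng(seed)
    g = np.r_[np.repeat("exposed", n // 2), np.repeat("comparator", n // 2)]
    mu = np.where(g == "exposed", mu0 * rr, mu0)
    y = np.zeros(n, dtype=int)
    pos = rng.random(n) < p_any
    y[pos] = _sample_ztnb(rng, mu[pos], alpha)
    return _rows(y, g)


def test_truncated_count_part_recovers_rate_ratio():
    rows = _ztnb_rows(20_000, 1.5, 0.8, seed=8)
    fit = fit_truncated_count_part(rows, SPEC0, family="negbin")
    err = abs(fit.params["group_exposed"] - np.log(1.5))
    assert err < 3 * fit.bse["group_exposed"]
    assert fit.alpha == pytest.approx(0.8, abs=0.1)


def test_offset_invariance_under_follow_up_doubling():
    rows = _ztnb_rows(4000, 1.5, 0.5, seed=12)
    fit1 = fit_truncated_count_part(rows, SPEC0, family="negbin")
    doubled = rows.assign(follow_up_days=rows["follow_up_days"] * 2)
    fit2 = fit_truncated_count_part(doubled, SPEC0, family="negbin")
    assert fit2.params["const"] == pytest.approx(
        fit1.params["const"] - np.log(2.0), abs=1e-4
    )
    assert fit2.params["group_exposed"] == pytest.approx(
        fit1.params["group_exposed"], abs=1e-4
    )


def test_alpha_boundary_falls_back_to_poisson():
    rng = np.random.default_rng(15)
    n = 3000
    g = np.repeat(["exposed", "comparator"], n // 2)
    mu = np.where(g == "exposed", 8.0, 5.0)
    y = _sample_ztnb(rng, mu, 0.0)  # equidispersed: alpha boundary
    rows = _rows(y, g)
    with pytest.warns(RuntimeWarning, match="Poisson"):
        fit = fit_truncated_count_part(rows, SPEC0, family="negbin")
    assert fit.kind == "truncated_poisson"
    assert abs(fit.params["group_exposed"] - np.log(8.0 / 5.0)) < 3 * fit.bse[
        "group_exposed"
    ]


def test_gamma_cost_part_recovers_cost_ratio():
    rng = np.random.default_rng(5)
    n = 20_000
    g = np.repeat(["exposed", "comparator"], n // 2)
    mean = np.where(g == "exposed", 1.44, 1.0) * 900.0
    cost = rng.gamma(2.0, mean / 2.0)
    rows = _rows(np.ones(n), g).rename(columns={"total_visits": "x"})
    rows["total_cost"] = cost
    spec = ModelSpec(outcome="total_cost", covariates=())
    fit = fit_gamma_cost_part(rows, spec)
    err = abs(fit.params["group_exposed"] - np.log(1.44))
    assert err < 3 * fit.bse["group_exposed"]
    assert fit.shape == pytest.approx(2.0, rel=0.1)

    # scale equivariance: x10 costs shift the intercept by log 10 only
    fit10 = fit_gamma_cost_part(rows.assign(total_cost=cost * 10), spec)
    assert fit10.params["const"] == pytest.approx(
        fit.params["const"] + np.log(10.0), abs=1e-8
    )
    assert fit10.params["group_exposed"] == pytest.approx(
        fit.params["group_exposed"], abs=1e-8
    )


def test_group_constant_costs_give_unit_ratio():
    cost = np.tile([100.0, 250.0, 400.0, 800.0], 50)
    rows = pd.DataFrame(
        {
            "total_cost": np.r_[cost, cost],
            "group": np.repeat(["exposed", "comparator"], len(cost)),
            "follow_up_days": 365,
        }
    )
    fit = fit_gamma_cost_part(rows, ModelSpec(outcome="total_cost", covariates=()))
    assert np.exp(fit.params["group_exposed"]) == pytest.approx(1.0, abs=1e-10)


def test_relabelling_groups_inverts_all_ratios(cohort):
    rows = cohort["rows"]
    spec = ModelSpec(outcome="total_visits",
                     covariates=("asthma", "mental_health"))
    fit = fit_two_part(rows, spec)
    swapped = rows.assign(
        group=rows["group"].map({"exposed": "comparator", "comparator": "exposed"})
    )
    fit_swapped = fit_two_part(swapped, spec)
    assert np.exp(fit_swapped.part1.params["group_exposed"]) == pytest.approx(
        1.0 / fit.odds_ratio[0], rel=1e-6
    )
    assert np.exp(fit_swapped.part2.params["group_exposed"]) == pytest.approx(
        1.0 / fit.rate_ratio[0], rel=1e-3
    )


def test_two_part_fit_recovers_generator_truth(cohort):
    fit = fit_two_part(cohort["rows"], ModelSpec("total_visits"))
    truth = cohort["truth"].implied_estimands()
    assert fit.family_used == "negbin"
    assert abs(
        fit.part1.params["group_exposed"] - np.log(truth["or_true"])
    ) < 3 * fit.part1.bse["group_exposed"]
    assert abs(
        fit.part2.params["group_exposed"]
        - np.log(truth["rr_conditional_contemporary"])
    ) < 3 * fit.part2.bse["group_exposed"]
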