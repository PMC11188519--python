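"""Cohort descriptives, missing-cost imputation, stratified and restricted
sensitivity analyses.

The descriptive table mirrors conventional baseline ("Table 1") practice:
counts with column percentages per factor level, chi-square tests (no
continuity correction) for categorical factors and a Welch t-test for age.
Stratum-specific effects come from group x stratum interaction terms, with
a likelihood-ratio test per model part for effect modification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import COSTED_CARE_TYPES
from .twopart import (
    GROUP_COL,
    Design,
    ModelSpec,
    fit_binomial_part,
    fit_gamma_cost_part,
    fit_truncated_count_part,
    overdispersion_check,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StratumEstimate",
    "table_one",
    "column_percentages",
    "impute_missing_costs",
    "stratified_analysis",
    "apply_restriction",
]

DEFAULT_TABLE_FACTORS = (
    "sex",
    "age_category",
    "ethnicity",
    "imd_quintile",
    "bmi_category",
    "region",
    "asthma",
    "mental_health",
    "comorbidity_level",
    "prior_covid_hospitalisation",
    "n_vaccine_doses_at_index",
    "positive_test_before_index",
)


def column_percentages(counts: dict) -> dict:
    """Column percentages (1 decimal) recomputed from level counts."""
    total = sum(counts.values())
    if total == 0:
        return {k: np.nan for k in counts}
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def table_one(
    patients: pd.DataFrame,
    group_col: str = "group",
    factors=None,
    continuous=("age",),
    pooled_t: bool = False,
) -> pd.DataFrame:
    """Baseline characteristics by group with chi-square / t-test p-values.

    Missing categorical values are tabulated as their own level.  Percentages
    are column percentages with the group total as denominator.
    """
    factors = [
        f for f in (DEFAULT_TABLE_FACTORS if factors is None else factors)
        if f in patients.columns
    ]
    grp = patients[group_col]
    groups = ("exposed", "comparator")
    n_by_group = {g: int((grp == g).sum()) for g in groups}
    records = []
    for f in factors:
        vals = patients[f].astype(str).replace({"nan": "missing", "": "missing"})
        levels = sorted(vals.unique())
        table = pd.crosstab(vals, grp)
        if len(levels) > 1 and all(g in table.columns for g in groups):
            chi2, p, _, _ = stats.chi2_contingency(
                table[list(groups)].to_numpy(), correction=False
            )
        else:
            p = np.nan  # single level: test not applicable
        for lv in levels:
            counts = {g: int(table.loc[lv, g]) if g in table.columns else 0
                      for g in groups}
            records.append(
                {
                    "factor": f,
                    "level": lv,
                    "overall_n": sum(counts.values()),
                    "overall_pct": round(
                        100.0 * sum(counts.values()) / max(len(patients), 1), 1
                    ),
                    "exposed_n": counts["exposed"],
                    "exposed_pct": round(
                        100.0 * counts["exposed"] / max(n_by_group["exposed"], 1), 1
                    ),
                    "comparator_n": counts["comparator"],
                    "comparator_pct": round(
                        100.0 * counts["comparator"] / max(n_by_group["comparator"], 1),
                        1,
                    ),
                    "p_value": p,
                }
            )
    for c in continuous:
        if c not in patients.columns:
            continue
        a = patients.loc[grp == "exposed", c].astype(float).dropna()
        b = patients.loc[grp == "comparator", c].astype(float).dropna()
        if len(a) > 1 and len(b) > 1:
            _, p = stats.ttest_ind(a, b, equal_var=pooled_t)
        else:
            p = np.nan
        records.append(
            {
                "factor": c,
                "level": "mean (SD)",
                "overall_n": len(a) + len(b),
                "overall_pct": np.nan,
                "exposed_n": round(a.mean(), 1),
                "exposed_pct": round(a.std(ddof=1), 1),
                "comparator_n": round(b.mean(), 1),
                "comparator_pct": round(b.std(ddof=1), 1),
                "p_value": p,
            }
        )
    return pd.DataFrame(records)


def impute_missing_costs(events: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Replace missing secondary-care costs by the care-type mean per event.

    Only missing entries change; observed costs (and GP/prescription rows,
    which are costed from unit prices) are untouched.  A care type whose
    costs are all missing cannot be imputed and raises.
    """
    out = events.copy()
    tally = {}
    costs = pd.to_numeric(out["cost"], errors="coerce")
    for t in COSTED_CARE_TYPES:
        sel = out["care_type"] == t
        missing = sel & costs.isna()
        n_miss = int(missing.sum())
        if n_miss == 0:
            tally[t] = 0
            continue
        observed = costs[sel & costs.notna()]
        if observed.empty:
            raise ValueError(f"all {t!r} costs missing; nothing to impute from")
        out.loc[missing, "cost"] = float(observed.mean())
        tally[t] = n_miss
    logger.info("imputed missing costs: %s", tally)
    return out, tally


@dataclass(frozen=True)
class StratumEstimate:
    variable: str
    level: str
    odds_ratio: float
    or_ci: tuple
    rate_ratio: float
    rr_ci: tuple
    lrt_p_part1: float
    lrt_p_part2: float
    lrt_df: int


def _lincom_ratio(part, terms: list, level: float = 0.95):
    """exp(sum of coefficients) with a Wald CI from the joint covariance."""
    idx = [t for t in terms if t in part.params.index]
    est = float(part.params[idx].sum())
    cov = part.cov_params.loc[idx, idx].to_numpy()
    se = float(np.sqrt(cov.sum()))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(est)), (float(np.exp(est - z * se)), float(np.exp(est + z * se)))


def stratified_analysis(
    rows: pd.DataFrame,
    spec: ModelSpec,
    stratify_by: str,
) -> list[StratumEstimate]:
    """Stratum-specific OR and RR (or cost ratio) via interaction terms.

    Fits the two-part model with a group x stratum interaction; stratum
    effects are linear combinations of the group main effect and the
    interaction coefficients.  Effect modification is assessed per part with
    a likelihood-ratio test against the no-interaction model,
    df = (levels - 1) per part.
    """
    if stratify_by not in spec.covariates:
        raise ValueError(f"{stratify_by!r} is not among the fitted covariates")
    cells = pd.crosstab(rows["group"], rows[stratify_by].astype(str))
    empty = [(g, lv) for g in cells.index for lv in cells.columns
             if cells.loc[g, lv] == 0]
    if empty:
        raise ValueError(f"empty group x stratum cell(s): {empty}")

    design_red = Design(rows, spec.covariates)
    design_full = Design(
        rows, spec.covariates, interactions=(("group", stratify_by),)
    )
    p1_red = fit_binomial_part(rows, spec, design_red)
    p1_full = fit_binomial_part(rows, spec, design_full)
    if spec.is_cost:
        p2_red = fit_gamma_cost_part(rows, spec, design_red)
        p2_full = fit_gamma_cost_part(rows, spec, design_full)
    else:
        _, family = overdispersion_check(rows, spec, design_red)
        p2_red = fit_truncated_count_part(rows, spec, family, design_red)
        p2_full = fit_truncated_count_part(rows, spec, family, design_full)

    levels = (
        design_full.levels.get(stratify_by)
        or sorted(rows[stratify_by].astype(str).unique())
    )
    df = len(levels) - 1
    lrt1 = max(2.0 * (p1_full.llf - p1_red.llf), 0.0)
    lrt2 = max(2.0 * (p2_full.llf - p2_red.llf), 0.0)
    p_lrt1 = float(stats.chi2.sf(lrt1, df))
    p_lrt2 = float(stats.chi2.sf(lrt2, df))

    out = []
    for lv in levels:
        terms = [GROUP_COL]
        if lv != levels[0]:
            terms.append(f"{GROUP_COL}:{stratify_by}[{lv}]")
        or_, or_ci = _lincom_ratio(p1_full, terms)
        rr, rr_ci = _lincom_ratio(p2_full, terms)
        out.append(
            StratumEstimate(
                variable=stratify_by,
                level=lv,
                odds_ratio=or_,
                or_ci=or_ci,
                rate_ratio=rr,
                rr_ci=rr_ci,
                lrt_p_part1=p_lrt1,
                lrt_p_part2=p_lrt2,
                lrt_df=df,
            )
        )
    return out


VALID_RESTRICTIONS = (
    "prior_gp_consult_within_1y",
    "positive_test_before_index",
    "drop_first_gp_event",
)


def apply_restriction(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    rule: str,
    index_dates: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cohort / event restrictions used in sensitivity analyses.

    ``prior_gp_consult_within_1y`` keeps patients with a GP contact in the
    year before the study start; ``positive_test_before_index`` keeps
    patients with a linked positive test; ``drop_first_gp_event`` removes
    each person's earliest post-index GP record before counting (and needs
    ``index_dates``, a patient_id-indexed Series).
    """
    if rule not in VALID_RESTRICTIONS:
        raise ValueError(
            f"unknown restriction {rule!r}; valid rules: {VALID_RESTRICTIONS}"
        )
    tally = {}
    if rule == "prior_gp_consult_within_1y":
        lo, hi = pd.Timestamp("2019-11-01"), pd.Timestamp("2020-11-01")
        gp = events[events["care_type"] == "gp"]
        d = pd.to_datetime(gp["date"])
        with_consult = set(gp.loc[(d >= lo) & (d < hi), "patient_id"])
        keep = patients["patient_id"].isin(with_consult)
        tally["excluded_patients"] = int((~keep).sum())
        return patients[keep].reset_index(drop=True), events, tally
    if rule == "positive_test_before_index":
        keep = patients["positive_test_before_index"].astype(bool)
        tally["excluded_patients"] = int((~keep).sum())
        return patients[keep].reset_index(drop=True), events, tally
    # drop_first_gp_event
    if index_dates is None:
        raise ValueError("drop_first_gp_event requires index_dates")
    ev = events.reset_index(drop=True)
    idx = ev["patient_id"].map(index_dates)
    is_post_gp = (
        (ev["care_type"] == "gp")
        & idx.notna()
        & (pd.to_datetime(ev["date"]) >= pd.to_datetime(idx))
    )
    firsts = (
        ev[is_post_gp]
        .sort_values(["patient_id", "date"], kind="mergesort")
        .groupby("patient_id", sort=False)
        .head(1)
        .index
    )
    tally["dropped_events"] = len(firsts)
    return patients, ev.drop(index=firsts).reset_index(drop=True), tally
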