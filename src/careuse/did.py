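"""Difference-in-difference comparison of pre-pandemic and post-index use.

Matched-set members registered since before March 2019 contribute two
analysis rows: a historical row over the fixed pre-pandemic year
(March 2019 - March 2020) and a contemporary row over their censored
post-index follow-up.  Both parts of the hurdle model are fitted with
group, period and group x period terms; the DID estimate is computed on the
absolute predicted scale as

    (exposed post - exposed pre) - (comparator post - comparator pre)

from the four marginally standardised predicted means, with the interaction
coefficients reported alongside.  The common-trend assumption is probed by
binning pre-period utilisation over calendar time per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .cohort import compute_follow_up_table
from .constants import (
    DAYS_PER_YEAR,
    DEFAULT_COVARIATES,
    HISTORICAL_END,
    HISTORICAL_START,
)
from .outcomes import build_analysis_rows
from .predict import bootstrap_ci, predict_average
from .twopart import (
    Design,
    ModelSpec,
    TwoPartFit,
    fit_binomial_part,
    fit_truncated_count_part,
    overdispersion_check,
)

logger = logging.getLogger(__name__)

__all__ = ["DIDResult", "build_did_rows", "fit_did", "check_common_trend"]

CELLS = tuple(product(("exposed", "comparator"), ("historical", "contemporary")))


@dataclass
class DIDResult:
    predicted_means: dict  # (group, period) -> visits per person-year
    did_estimate: float
    within_group_differences: dict  # group -> post - pre
    interaction_part1: tuple  # (coef, se) on the log-odds scale
    interaction_part2: tuple  # (coef, se) on the log-rate scale
    fit: TwoPartFit
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_bootstrap: int = 0
    extras: dict = field(default_factory=dict)


def build_did_rows(
    matched_sets: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    unit_costs,
    follow_ups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Stacked historical + contemporary rows for members with both periods."""
    if follow_ups is None:
        follow_ups = compute_follow_up_table(matched_sets, patients)
    follow_ups = follow_ups[~follow_ups["zero_length"]]
    hist = build_analysis_rows(
        matched_sets, follow_ups, events, patients, unit_costs, "historical"
    )
    cont = build_analysis_rows(
        matched_sets, follow_ups, events, patients, unit_costs, "contemporary"
    )
    key = ["patient_id", "set_id"]
    both = set(map(tuple, hist[key].values)) & set(map(tuple, cont[key].values))
    n_dropped = (len(hist) - len(both)) + (len(cont) - len(both))
    if n_dropped:
        logger.info("excluded %d single-period person-rows from DID", n_dropped)
    keep = lambda df: df[df[key].apply(tuple, axis=1).isin(both)]  # noqa: E731
    return pd.concat([keep(hist), keep(cont)], ignore_index=True)


def fit_did(
    rows: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    outcome: str = "total_visits",
    family_override: str | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> DIDResult:
    """Two-part DID fit with marginally standardised four-cell means."""
    counts = rows.groupby(["group", "period"], observed=True).size()
    for cell in CELLS:
        if counts.get(cell, 0) == 0:
            raise ValueError(f"empty group x period cell {cell}")
    spec = ModelSpec(outcome=outcome, covariates=covariates,
                     family_override=family_override)
    design = Design(
        rows, covariates, include_period=True, interactions=(("group", "period"),)
    )
    part1 = fit_binomial_part(rows, spec, design)
    ratio, family = overdispersion_check(rows, spec, design)
    part2 = fit_truncated_count_part(rows, spec, family, design)
    fit = TwoPartFit(
        spec=spec,
        design=design,
        part1=part1,
        part2=part2,
        family_used=family,
        n_rows=len(rows),
        n_nonzero=int((rows[outcome] > 0).sum()),
        dispersion_ratio=ratio,
    )
    # standardise over distinct persons (covariates repeat across periods)
    basis = rows.drop_duplicates(["patient_id", "set_id"])
    means = {
        (g, p): predict_average(fit, basis, group=g, period=p) for g, p in CELLS
    }
    result = _did_from_means(means)
    term = "group_exposed:period_contemporary"
    did = DIDResult(
        predicted_means=means,
        did_estimate=result["did"],
        within_group_differences=result["within"],
        interaction_part1=(float(part1.params[term]), float(part1.bse[term])),
        interaction_part2=(float(part2.params[term]), float(part2.bse[term])),
        fit=fit,
    )
    if n_bootstrap:
        def refit(sample):
            return fit_did(
                sample, covariates=covariates, outcome=outcome,
                family_override=family_override,
            ).did_estimate

        lo, hi = bootstrap_ci(refit, rows, n_reps=n_bootstrap, seed=seed)
        did.ci_low, did.ci_high, did.n_bootstrap = lo, hi, n_bootstrap
    return did


def _did_from_means(means: dict) -> dict:
    within = {
        g: means[(g, "contemporary")] - means[(g, "historical")]
        for g in ("exposed", "comparator")
    }
    return {"within": within, "did": within["exposed"] - within["comparator"]}


def check_common_trend(
    events: pd.DataFrame,
    members: pd.DataFrame,
    bins: int = 4,
    window=(HISTORICAL_START, HISTORICAL_END),
    plot_path=None,
) -> pd.DataFrame:
    """Per-bin average visits per person-year by group over the pre-period.

    ``members`` needs patient_id, group and (optionally) registration_start /
    registration_end / death_date to truncate person-time.  Returns one row
    per (group, bin) with the between-group gap; a bin with no person-time
    is reported with a zero-person-time flag rather than dropped.
    """
    if bins < 2:
        raise ValueError("need at least 2 pre-period bins")
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    edges = pd.date_range(start, end, periods=bins + 1)
    ev = events.merge(members[["patient_id", "group"]], on="patient_id", how="inner")
    ev = ev.drop_duplicates(["patient_id", "care_type", "date"])
    dates = pd.to_datetime(ev["date"])

    cov_start = pd.to_datetime(
        members.get("registration_start", pd.Series(start, index=members.index))
    ).fillna(start)
    cov_end_cols = [
        pd.to_datetime(members[c])
        for c in ("registration_end", "death_date")
        if c in members.columns
    ]
    cov_end = (
        pd.concat(cov_end_cols, axis=1).min(axis=1, skipna=True)
        if cov_end_cols
        else pd.Series(end, index=members.index)
    ).fillna(end)

    records = []
    for g, sub in members.groupby("group", observed=True):
        for b in range(bins):
            lo, hi = edges[b], edges[b + 1]
            ov_start = cov_start[sub.index].clip(lower=lo)
            ov_end = cov_end[sub.index].clip(upper=hi)
            days = (ov_end - ov_start).dt.days.clip(lower=0)
            person_years = float(days.sum() / DAYS_PER_YEAR)
            mask = (
                (ev["group"] == g) & (dates >= lo) & (dates < hi)
            )
            visits = int(mask.sum())
            records.append(
                {
                    "group": g,
                    "bin": b,
                    "bin_start": lo,
                    "bin_end": hi,
                    "visits": visits,
                    "person_years": person_years,
                    "rate": visits / person_years if person_years > 0 else np.nan,
                    "zero_person_time": person_years == 0,
                }
            )
    table = pd.DataFrame(records)
    gaps = table.pivot(index="bin", columns="group", values="rate")
    if {"exposed", "comparator"} <= set(gaps.columns):
        gap = (gaps["exposed"] - gaps["comparator"]).rename("gap")
        table = table.merge(gap, left_on="bin", right_index=True, how="left")
    else:
        table["gap"] = np.nan
    if plot_path is not None:
        _plot_trend(table, plot_path)
    return table


def _plot_trend(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in table.groupby("group", observed=True):
        ax.plot(sub["bin_start"], sub["rate"], marker="o", label=g)
    ax.set_xlabel("pre-period bin start")
    ax.set_ylabel("visits per person-year")
    ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
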