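"""Synthetic EHR cohort generator with known ground-truth effects.

Real primary-care records of the kind this pipeline analyses are
re-identifiable and cannot be shared, so every downstream stage is exercised
on simulated data whose estimands are known exactly.  The generator emulates
the statistical structure of a matched long-COVID utilisation study:

* an exposed group (long COVID diagnosis) and a large undiagnosed comparator
  pool, 1:5 matchable on age, sex and region;
* demographic and clinical covariates drawn from the published marginal
  distributions of such a cohort (stored in :data:`COHORT_REFERENCE_COUNTS`);
* zero-inflated, right-skewed utilisation: a person-level hurdle (any use
  vs none) followed by a zero-truncated NB2 total count, allocated across
  five care types and scattered uniformly over the observation window;
* Gamma-distributed secondary-care costs with a configurable exposed:
  comparator cost ratio and a small fraction of missing cost records;
* a difference-in-difference structure: the latent exposed/comparator rate
  ratio applies in both the pre-pandemic and post-index periods, and
  ``did_effect_true`` adds an extra log-rate shift to exposed subjects'
  contemporary period.

Because the hurdle is applied to the person-level total and the total is
zero-truncated NB2, the downstream two-part estimator is correctly
specified and parameter-recovery tests have exact truths (see
:meth:`GroundTruth.implied_estimands`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .constants import (
    ADMIN_END,
    CARE_TYPES,
    COSTED_CARE_TYPES,
    DAYS_PER_YEAR,
    PERIOD_LABELS,
    STUDY_START,
)
from .outcomes import UnitCostTable
from .truncated import _logp0, truncated_mean

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "COHORT_REFERENCE_COUNTS",
    "generate_population",
    "generate_events",
    "generate_event_stream",
    "default_unit_costs",
]

#: published marginal counts (exposed, comparator) of the matched cohort the
#: generator emulates; percentages in descriptive tables are recomputed from
#: these counts.  Factors matched on (age band, sex, region) have identical
#: group proportions by construction.
COHORT_REFERENCE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "sex": {"Female": (33805, 168984), "Male": (19183, 95883)},
    "age_category": {
        "18-29": (6638, 33188),
        "30-39": (10050, 50235),
        "40-49": (13241, 66196),
        "50-59": (13236, 66153),
        "60-69": (6199, 30984),
        "70+": (3624, 18111),
    },
    "ethnicity": {
        "White": (40972, 195292),
        "Mixed": (539, 2801),
        "South Asian": (3053, 16227),
        "Black": (832, 5622),
        "Other": (655, 5237),
        "missing": (6937, 39688),
    },
    "imd_quintile": {
        "1 least deprived": (10457, 52359),
        "2": (10446, 52341),
        "3": (10478, 51978),
        "4": (10349, 52021),
        "5 most deprived": (10272, 51331),
        "missing": (986, 4837),
    },
    "region": {
        "East": (10162, 50807),
        "East Midlands": (7513, 37562),
        "London": (2400, 11995),
        "North East": (4161, 20805),
        "North West": (6068, 30340),
        "South East": (3707, 18535),
        "South West": (8267, 41353),
        "West Midlands": (1675, 8374),
        "Yorkshire and The Humber": (9020, 45096),
    },
    "asthma": {"False": (40618, 223151), "True": (12370, 41716)},
    "mental_health": {"False": (34320, 201189), "True": (18668, 63678)},
    "n_comorbidities": {
        "0": (43476, 225058),
        "1": (7997, 34450),
        "2": (1296, 4737),
        "3+": (219, 622),
    },
    "prior_covid_hospitalisation": {"False": (48333, 263162), "True": (4655, 1705)},
    "n_vaccine_doses_at_index": {
        "0": (8454, 54698),
        "1": (5215, 23771),
        "2": (17259, 80899),
        "3+": (22060, 105499),
    },
    "positive_test_before_index": {"False": (32006, 182448), "True": (20982, 82419)},
}

GROUP_TOTALS = (52988, 264867)  # exposed, comparator

#: BMI marginals in the source table are internally inconsistent as printed,
#: so BMI uses a generic plausible adult distribution instead.
BMI_DISTRIBUTION = {
    "Underweight": 0.02,
    "Normal weight": 0.34,
    "Overweight": 0.33,
    "Obese": 0.23,
    "missing": 0.08,
}

_AGE_BOUNDS = {
    "18-29": (18, 30),
    "30-39": (30, 40),
    "40-49": (40, 50),
    "50-59": (50, 60),
    "60-69": (60, 70),
    "70+": (70, 91),
}

#: multinomial allocation of total visits across care types
DEFAULT_TYPE_SHARES = {
    "gp": 0.35,
    "prescription": 0.40,
    "ae": 0.03,
    "admission": 0.02,
    "outpatient": 0.20,
}

#: BNF prescription chapters: chapter -> (sampling weight, unit cost, pounds)
DEFAULT_BNF_CHAPTERS = {
    "01": (0.10, 8.0),
    "02": (0.16, 12.0),
    "03": (0.10, 18.0),
    "04": (0.18, 15.0),
    "05": (0.08, 10.0),
    "06": (0.10, 22.0),
    "07": (0.04, 14.0),
    "08": (0.04, 55.0),
    "09": (0.08, 9.0),
    "10": (0.12, 11.0),
}

#: mean recorded cost per secondary-care event for the comparator group (£)
EVENT_COST_MEANS = {"ae": 160.0, "admission": 2600.0, "outpatient": 140.0}

_SUPPORTED_COVARIATE_EFFECTS = (
    "asthma",
    "mental_health",
    "n_comorbidities",
    "age_decades",
    "prior_covid_hospitalisation",
    "sex_male",
)


def default_unit_costs() -> UnitCostTable:
    """Unit-cost table matching the generator's BNF chapter set."""
    return UnitCostTable(
        bnf_chapter_costs={ch: cost for ch, (_, cost) in DEFAULT_BNF_CHAPTERS.items()}
    )


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters; the defaults are the package's study conditions.

    ``p_nonzero_*`` are the person-level hurdle probabilities of any
    healthcare use; ``rate_ratio_true`` is the persistent latent exposed:
    comparator conditional event-rate ratio; ``did_effect_true`` is the
    additional log-rate shift in the exposed group's contemporary
    (post-index) period; ``base_rate`` is in events per person-year per care
    type for a reference comparator.
    """

    n_exposed: int = 2000
    comparator_pool_multiplier: float = 10.0
    p_nonzero_exposed: float = 0.95
    p_nonzero_comparator: float = 0.70
    rate_ratio_true: float = 1.49
    base_rate: float = 3.2
    dispersion_alpha: float = 0.8
    cost_ratio_true: float = 1.44
    gamma_shape: float = 2.0
    did_effect_true: float = 0.3570
    covariate_effect_map: Mapping[str, float] = field(
        default_factory=lambda: {
            "asthma": 0.15,
            "mental_health": 0.20,
            "n_comorbidities": 0.12,
            "age_decades": 0.05,
        }
    )
    missing_cost_fraction: float = 0.02
    seed: int = 42
    historical_coverage_fraction: float = 0.9

    def __post_init__(self):
        if not isinstance(self.n_exposed, (int, np.integer)) or isinstance(
            self.n_exposed, bool
        ):
            raise ValueError("n_exposed must be an integer")
        if self.n_exposed < 1:
            raise ValueError("n_exposed must be >= 1")
        for name in (
            "p_nonzero_exposed",
            "p_nonzero_comparator",
            "missing_cost_fraction",
            "historical_coverage_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "comparator_pool_multiplier",
            "rate_ratio_true",
            "base_rate",
            "cost_ratio_true",
            "gamma_shape",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dispersion_alpha < 0:
            raise ValueError("dispersion_alpha must be non-negative")
        for key in self.covariate_effect_map:
            if key not in _SUPPORTED_COVARIATE_EFFECTS:
                raise ValueError(
                    f"unknown covariate effect {key!r}; supported: "
                    f"{_SUPPORTED_COVARIATE_EFFECTS}"
                )

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Effect parameters actually used plus per-patient latent assignments.

    ``frame`` holds one row per patient: exposure status, hurdle probability
    and the latent comparator-counterfactual event rate per person-year
    (``mu_year_base``, i.e. before the group rate ratio and DID shift).
    """

    params: SimulationParams
    frame: pd.DataFrame

    def implied_estimands(
        self,
        unit_costs: UnitCostTable | None = None,
        patient_ids=None,
    ) -> dict:
        """Closed-form estimands implied by the generative parameters.

        Predicted means are standardised over the generated covariate
        distribution at one person-year, mirroring the pipeline's marginal
        standardisation, so recovery tests compare like with like.  Pass
        ``patient_ids`` to standardise over an analysis cohort (e.g. the
        matched members) instead of the whole generated population.
        """
        p = self.params
        uc = default_unit_costs() if unit_costs is None else unit_costs
        alpha = p.dispersion_alpha
        frame = self.frame
        if patient_ids is not None:
            frame = frame[frame["patient_id"].isin(set(patient_ids))]
        mu0 = frame["mu_year_base"].to_numpy()
        mu_hist_c, mu_post_c = mu0, mu0
        mu_hist_e = mu0 * p.rate_ratio_true
        mu_post_e = mu0 * p.rate_ratio_true * np.exp(p.did_effect_true)

        def pm(p_nonzero, mu):
            return p_nonzero * float(np.mean(truncated_mean(mu, alpha)))

        pm_hist_e = pm(p.p_nonzero_exposed, mu_hist_e)
        pm_hist_c = pm(p.p_nonzero_comparator, mu_hist_c)
        pm_post_e = pm(p.p_nonzero_exposed, mu_post_e)
        pm_post_c = pm(p.p_nonzero_comparator, mu_post_c)

        # expected cost per visit, by group (secondary events carry the
        # Gamma cost; GP and prescriptions are costed from the unit table)
        mean_chapter = sum(w * c for w, c in DEFAULT_BNF_CHAPTERS.values())
        shares = DEFAULT_TYPE_SHARES

        def cost_per_visit(ratio):
            secondary = sum(
                shares[t] * EVENT_COST_MEANS[t] * ratio for t in COSTED_CARE_TYPES
            )
            return (
                shares["gp"] * uc.gp_consultation_cost
                + shares["prescription"] * mean_chapter
                + secondary
            )

        c_comp = cost_per_visit(1.0)
        c_exp = cost_per_visit(p.cost_ratio_true)
        cm_post_e = float(np.mean(truncated_mean(mu_post_e, alpha)))
        cm_post_c = float(np.mean(truncated_mean(mu_post_c, alpha)))

        log_or = special.logit(p.p_nonzero_exposed) - special.logit(
            p.p_nonzero_comparator
        )
        return {
            "or_true": float(np.exp(log_or)),
            "log_or_true": float(log_or),
            "rr_conditional_historical": p.rate_ratio_true,
            "rr_conditional_contemporary": p.rate_ratio_true
            * float(np.exp(p.did_effect_true)),
            "cost_ratio_conditional": c_exp * cm_post_e / (c_comp * cm_post_c),
            "predicted_mean_visits": {
                ("exposed", "historical"): pm_hist_e,
                ("comparator", "historical"): pm_hist_c,
                ("exposed", "contemporary"): pm_post_e,
                ("comparator", "contemporary"): pm_post_c,
            },
            "predicted_mean_cost": {
                "exposed": p.p_nonzero_exposed * c_exp * cm_post_e,
                "comparator": p.p_nonzero_comparator * c_comp * cm_post_c,
            },
            "did_true": (pm_post_e - pm_hist_e) - (pm_post_c - pm_hist_c),
        }


# ---------------------------------------------------------------------------
# population generation


def _sample_factor(rng, counts_by_level, group_idx, n):
    levels = list(counts_by_level)
    weights = np.array([counts_by_level[lv][group_idx] for lv in levels], dtype=float)
    return rng.choice(levels, size=n, p=weights / weights.sum())


def _random_dates(rng, start: pd.Timestamp, end: pd.Timestamp, n: int) -> pd.Series:
    """Uniform dates in [start, end] (whole days)."""
    span = (end - start).days
    return start + pd.to_timedelta(rng.integers(0, span + 1, size=n), unit="D")


def covariate_log_effect(patients: pd.DataFrame, effect_map: Mapping[str, float]):
    """Linear predictor contribution of covariates on the log-rate scale."""
    eta = np.zeros(len(patients))
    for name, beta in effect_map.items():
        if name == "age_decades":
            x = (patients["age"].to_numpy(float) - 48.0) / 10.0
        elif name == "sex_male":
            x = (patients["sex"] == "Male").to_numpy(float)
        elif name == "n_comorbidities":
            x = patients["n_comorbidities"].to_numpy(float)
        elif name in ("asthma", "mental_health", "prior_covid_hospitalisation"):
            x = patients[name].astype(bool).to_numpy(float)
        else:  # pragma: no cover - guarded by SimulationParams validation
            raise ValueError(f"unknown covariate effect {name!r}")
        eta += beta * x
    return eta


def generate_population(
    params: SimulationParams,
    study_start: pd.Timestamp = STUDY_START,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the patient table and its ground truth.

    Returns ``params.n_exposed`` exposed patients (each with a long COVID
    diagnosis date) plus ``n_exposed * comparator_pool_multiplier``
    undiagnosed pool patients.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_exp = params.n_exposed
    n_comp = int(round(n_exp * params.comparator_pool_multiplier))
    n = n_exp + n_comp
    exposed = np.zeros(n, dtype=bool)
    exposed[:n_exp] = True

    frames = {}
    # matched-on factors: identical distribution in both groups (use the
    # combined reference counts)
    combined = {
        f: {lv: (a + b,) for lv, (a, b) in COHORT_REFERENCE_COUNTS[f].items()}
        for f in ("age_category", "sex", "region")
    }
    for f in ("age_category", "sex", "region"):
        frames[f] = _sample_factor(rng, combined[f], 0, n)
    # group-specific factors
    for f in (
        "ethnicity",
        "imd_quintile",
        "asthma",
        "mental_health",
        "n_comorbidities",
        "prior_covid_hospitalisation",
        "n_vaccine_doses_at_index",
        "positive_test_before_index",
    ):
        col = np.empty(n, dtype=object)
        col[exposed] = _sample_factor(rng, COHORT_REFERENCE_COUNTS[f], 0, n_exp)
        col[~exposed] = _sample_factor(rng, COHORT_REFERENCE_COUNTS[f], 1, n_comp)
        frames[f] = col

    bmi_levels = list(BMI_DISTRIBUTION)
    frames["bmi_category"] = rng.choice(
        bmi_levels, size=n, p=np.array(list(BMI_DISTRIBUTION.values()))
    )

    age = np.empty(n, dtype=int)
    for band, (lo, hi) in _AGE_BOUNDS.items():
        mask = frames["age_category"] == band
        age[mask] = rng.integers(lo, hi, size=int(mask.sum()))

    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i:07d}" for i in range(n)],
            "age": age,
            "sex": frames["sex"],
            "region": frames["region"],
            "ethnicity": frames["ethnicity"],
            "imd_quintile": frames["imd_quintile"],
            "bmi_category": frames["bmi_category"],
            "asthma": frames["asthma"] == "True",
            "mental_health": frames["mental_health"] == "True",
            "n_comorbidities": np.where(
                frames["n_comorbidities"] == "3+", 3, frames["n_comorbidities"]
            ).astype(int),
            "prior_covid_hospitalisation": frames["prior_covid_hospitalisation"]
            == "True",
            "n_vaccine_doses_at_index": frames["n_vaccine_doses_at_index"],
            "positive_test_before_index": frames["positive_test_before_index"]
            == "True",
        }
    )

    # registration intervals: a configurable fraction covers the full
    # March 2019 - January 2023 span; the rest register later
    covered = rng.random(n) < params.historical_coverage_fraction
    reg_start = pd.Series(pd.NaT, index=range(n))
    reg_start[covered] = _random_dates(
        rng, pd.Timestamp("2015-01-01"), pd.Timestamp("2019-02-28"), int(covered.sum())
    )
    reg_start[~covered] = _random_dates(
        rng,
        pd.Timestamp("2019-03-02"),
        pd.Timestamp("2020-07-31"),
        int((~covered).sum()),
    )
    dereg = rng.random(n) < 0.10
    reg_end = pd.Series(pd.Timestamp("2023-06-30"), index=range(n))
    reg_end[dereg] = _random_dates(
        rng, pd.Timestamp("2021-06-01"), ADMIN_END, int(dereg.sum())
    )

    death = pd.Series(pd.NaT, index=range(n))
    dies = rng.random(n) < 0.015
    death[dies] = _random_dates(rng, study_start, ADMIN_END, int(dies.sum()))

    diag = pd.Series(pd.NaT, index=range(n))
    diag[:n_exp] = _random_dates(
        rng, study_start, pd.Timestamp("2022-01-31"), n_exp
    )
    resolved = pd.Series(pd.NaT, index=range(n))
    res_mask = exposed & (rng.random(n) < 0.05)
    resolved[res_mask] = diag[res_mask] + pd.to_timedelta(
        rng.integers(30, 401, size=int(res_mask.sum())), unit="D"
    )

    patients["registration_start"] = pd.to_datetime(reg_start.values)
    patients["registration_end"] = pd.to_datetime(reg_end.values)
    patients["death_date"] = pd.to_datetime(death.values)
    patients["longcovid_diagnosis_date"] = pd.to_datetime(diag.values)
    patients["longcovid_resolved_date"] = pd.to_datetime(resolved.values)
    patients["practice_id"] = [f"pr{i:03d}" for i in rng.integers(0, 100, size=n)]
    patients["practice_coding"] = True

    mu_year_base = (
        params.base_rate
        * len(CARE_TYPES)
        * np.exp(covariate_log_effect(patients, params.covariate_effect_map))
    )
    truth = GroundTruth(
        params=params,
        frame=pd.DataFrame(
            {
                "patient_id": patients["patient_id"],
                "exposed": exposed,
                "p_nonzero": np.where(
                    exposed, params.p_nonzero_exposed, params.p_nonzero_comparator
                ),
                "mu_year_base": mu_year_base,
            }
        ),
    )
    return patients, truth


# ---------------------------------------------------------------------------
# event-stream generation


def _sample_ztnb(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Zero-truncated NB2 (or Poisson) draws via the inverse CDF."""
    p0 = np.exp(_logp0(mu, alpha))
    u = p0 + rng.random(len(mu)) * (1.0 - p0)
    u = np.clip(u, None, 1.0 - 1e-12)
    if alpha == 0.0:
        y = stats.poisson.ppf(u, mu)
    else:
        k = 1.0 / alpha
        y = stats.nbinom.ppf(u, k, k / (k + mu))
    return np.maximum(y, 1.0).astype(np.int64)


def generate_events(
    patients: pd.DataFrame,
    windows: pd.DataFrame,
    params: SimulationParams,
    period_label: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate utilisation events for each patient over its window.

    ``windows`` has columns ``patient_id, start, end`` (half-open) and may
    repeat a patient over disjoint windows (e.g. a spell served as a
    comparator before their own diagnosis, then their own exposed
    follow-up).  The hurdle probability and latent rate depend on exposure
    status — taken from an optional boolean ``exposed`` column in
    ``windows`` (the analysis role over that window) or, failing that, from
    the presence of a diagnosis date.  Exposed contemporary windows
    additionally apply ``did_effect_true``.
    """
    if period_label not in PERIOD_LABELS:
        raise ValueError(
            f"unknown period_label {period_label!r}; expected one of {PERIOD_LABELS}"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    w = windows.merge(patients, on="patient_id", how="left", validate="m:1")
    start = pd.to_datetime(w["start"])
    end = pd.to_datetime(w["end"])
    days = (end - start).dt.days.to_numpy()
    if np.any(days <= 0):
        bad = w.loc[days <= 0, "patient_id"].tolist()
        raise ValueError(f"empty observation window for patients {bad[:5]}")

    if "exposed" in windows.columns:
        exposed = w["exposed"].astype(bool).to_numpy()
    else:
        exposed = w["longcovid_diagnosis_date"].notna().to_numpy()
    years = days / DAYS_PER_YEAR
    eta = covariate_log_effect(w, params.covariate_effect_map)
    log_mu = (
        np.log(params.base_rate * len(CARE_TYPES))
        + eta
        + np.log(params.rate_ratio_true) * exposed
        + np.log(years)
    )
    if period_label == "contemporary":
        log_mu = log_mu + params.did_effect_true * exposed
    mu = np.exp(log_mu)
    p_nonzero = np.where(
        exposed, params.p_nonzero_exposed, params.p_nonzero_comparator
    )
    positive = rng.random(len(w)) < p_nonzero
    totals = np.zeros(len(w), dtype=np.int64)
    if positive.any():
        totals[positive] = _sample_ztnb(rng, mu[positive], params.dispersion_alpha)

    shares = np.array([DEFAULT_TYPE_SHARES[t] for t in CARE_TYPES])
    alloc = rng.multinomial(totals, shares)

    chapters = list(DEFAULT_BNF_CHAPTERS)
    ch_weights = np.array([w_ for w_, _ in DEFAULT_BNF_CHAPTERS.values()])
    ch_weights = ch_weights / ch_weights.sum()

    pieces = []
    start_np = start.to_numpy()
    pid = w["patient_id"].to_numpy()
    for j, care_type in enumerate(CARE_TYPES):
        n_ev = alloc[:, j]
        total = int(n_ev.sum())
        if total == 0:
            continue
        rep = np.repeat(np.arange(len(w)), n_ev)
        offsets = rng.integers(0, np.repeat(days, n_ev))
        dates = start_np[rep] + offsets.astype("timedelta64[D]")
        piece = pd.DataFrame(
            {
                "patient_id": pid[rep],
                "date": dates,
                "care_type": care_type,
                "code": "",
                "cost": np.nan,
                "end_date": pd.NaT,
            }
        )
        if care_type == "prescription":
            piece["code"] = rng.choice(chapters, size=total, p=ch_weights)
        if care_type in COSTED_CARE_TYPES:
            ratio = np.where(exposed[rep], params.cost_ratio_true, 1.0)
            mean_cost = EVENT_COST_MEANS[care_type] * ratio
            piece["cost"] = rng.gamma(
                params.gamma_shape, mean_cost / params.gamma_shape
            )
            missing = rng.random(total) < params.missing_cost_fraction
            piece.loc[missing, "cost"] = np.nan
        if care_type == "admission":
            piece["end_date"] = piece["date"] + pd.to_timedelta(
                rng.integers(1, 11, size=total), unit="D"
            )
        pieces.append(piece)

    if not pieces:
        events = pd.DataFrame(
            columns=["patient_id", "date", "care_type", "code", "cost", "end_date"]
        )
        events["date"] = pd.to_datetime(events["date"])
        events["end_date"] = pd.to_datetime(events["end_date"])
        return events
    events = pd.concat(pieces, ignore_index=True)
    events["date"] = pd.to_datetime(events["date"])
    events["end_date"] = pd.to_datetime(events["end_date"])
    return events.sort_values(
        ["patient_id", "date", "care_type"], kind="mergesort"
    ).reset_index(drop=True)


def generate_event_stream(
    patient: pd.Series,
    window: tuple,
    params: SimulationParams,
    period_label: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-patient convenience wrapper around :func:`generate_events`."""
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if end <= start:
        raise ValueError("empty observation window")
    patients = patient.to_frame().T if isinstance(patient, pd.Series) else patient
    windows = pd.DataFrame(
        {"patient_id": patients["patient_id"], "start": start, "end": end}
    )
    return generate_events(patients, windows, params, period_label, rng=rng)
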