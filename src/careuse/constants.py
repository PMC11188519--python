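"""Study constants shared across pipeline stages.

Dates follow the study design: cohort entry opens 2020-11-01, administrative
censoring at 2023-01-31, and the pre-pandemic ("historical") comparison
window is the year from March 2019 to March 2020.  All date intervals in the
package are half-open ``[start, end)`` and day counts are ``end - start``.
"""

from __future__ import annotations

import pandas as pd

CARE_TYPES = ("gp", "prescription", "ae", "admission", "outpatient")

#: care types whose costs are recorded per event (NHS-provided tariffs);
#: GP and prescription costs are assembled from unit costs instead
COSTED_CARE_TYPES = ("ae", "admission", "outpatient")

STUDY_START = pd.Timestamp("2020-11-01")
ADMIN_END = pd.Timestamp("2023-01-31")
HISTORICAL_START = pd.Timestamp("2019-03-01")
HISTORICAL_END = pd.Timestamp("2020-03-01")

OUTCOME_WINDOW_DAYS = 365
MIN_REGISTRATION_DAYS = 90
MATCHING_RATIO = 5
MATCH_VARS = ("age", "sex", "region")

#: average cost of a GP consultation, pounds per visit (2021/22 tariff)
GP_CONSULTATION_COST = 41.0

DAYS_PER_YEAR = 365.25

PERIOD_LABELS = ("historical", "contemporary")

#: covariate columns used by the default adjusted models
DEFAULT_COVARIATES = (
    "age_category",
    "sex",
    "ethnicity",
    "imd_quintile",
    "region",
    "asthma",
    "mental_health",
    "comorbidity_level",
    "prior_covid_hospitalisation",
    "n_vaccine_doses_at_index",
)

AGE_BINS = (18, 30, 40, 50, 60, 70, 120)
AGE_LABELS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70+")


def age_category(age) -> pd.Categorical:
    """Bin integer ages into the study's six age bands."""
    return pd.cut(
        pd.Series(age), bins=list(AGE_BINS), labels=list(AGE_LABELS), right=False
    ).astype(str)
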