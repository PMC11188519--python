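"""The two-part (hurdle) model: logistic first part, zero-truncated count or
Gamma second part, covariate-adjusted with person-time offsets.

Utilisation and cost outcomes in primary-care cohorts are zero-inflated and
right-skewed, so a single GLM fits poorly.  The two-part decomposition
models (1) the probability of any use with logistic regression and (2) the
amount of use among users with a zero-truncated NB2 (or Poisson) regression
for counts, or a log-link Gamma GLM for costs.  Log person-years enter the
second-part models as offsets, making ``exp(group coefficient)`` a rate
ratio (or cost ratio); the first part reports an odds ratio.  Whether the
count part is Poisson or negative binomial is decided by the ratio of
residual deviance to residual degrees of freedom of a Poisson fit
(> 1 means overdispersion, NB2 is used).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .constants import DAYS_PER_YEAR, DEFAULT_COVARIATES
from .truncated import TruncatedCountModel

__all__ = [
    "ModelSpec",
    "Design",
    "FitPart",
    "TwoPartFit",
    "fit_binomial_part",
    "overdispersion_check",
    "fit_truncated_count_part",
    "fit_gamma_cost_part",
    "fit_two_part",
    "estimates_frame",
]

GROUP_COL = "group_exposed"
PERIOD_COL = "period_contemporary"


@dataclass(frozen=True)
class ModelSpec:
    """What to model: outcome column, adjustment set, family choices."""

    outcome: str = "total_visits"
    covariates: tuple = DEFAULT_COVARIATES
    family_override: str | None = None  # {"poisson", "negbin"} or None
    dispersion_threshold: float = 1.0

    @property
    def is_cost(self) -> bool:
        return "cost" in self.outcome


class Design:
    """Design-matrix builder with remembered categorical levels.

    Categorical covariates are dummy-encoded against their first (sorted)
    level; the exposure indicator is always included.  Remembering levels at
    construction keeps bootstrap refits and counterfactual prediction
    matrices column-aligned, and lets prediction fail loudly on a level the
    fit never saw.
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        covariates=DEFAULT_COVARIATES,
        include_period: bool = False,
        interactions: tuple = (),
    ):
        self.covariates = tuple(c for c in covariates if c != "group")
        self.include_period = include_period
        self.interactions = tuple(tuple(pair) for pair in interactions)
        self.levels: dict[str, list] = {}
        for c in self.covariates:
            s = rows[c]
            if s.dtype == bool or np.issubdtype(s.dtype, np.number):
                continue
            self.levels[c] = sorted(map(str, s.dropna().unique()))

    def _encode(self, rows, col, group=None, period=None) -> pd.DataFrame:
        if col == "group":
            vals = (
                pd.Series(group, index=rows.index)
                if group is not None
                else rows["group"]
            )
            return pd.DataFrame({GROUP_COL: (vals == "exposed").astype(float)})
        if col == "period":
            vals = (
                pd.Series(period, index=rows.index)
                if period is not None
                else rows["period"]
            )
            return pd.DataFrame(
                {PERIOD_COL: (vals == "contemporary").astype(float)}
            )
        s = rows[col]
        if col in self.levels:
            levels = self.levels[col]
            sv = s.astype(str)
            unseen = sorted(set(sv.unique()) - set(levels))
            if unseen:
                raise ValueError(
                    f"covariate {col!r} has level(s) {unseen} absent from the fit"
                )
            return pd.DataFrame(
                {
                    f"{col}[{lv}]": (sv == lv).astype(float)
                    for lv in levels[1:]
                },
                index=rows.index,
            )
        return pd.DataFrame({col: s.astype(float)})

    def matrix(self, rows: pd.DataFrame, group=None, period=None) -> pd.DataFrame:
        parts = [pd.DataFrame({"const": 1.0}, index=rows.index)]
        parts.append(self._encode(rows, "group", group=group))
        if self.include_period:
            parts.append(self._encode(rows, "period", period=period))
        for c in self.covariates:
            parts.append(self._encode(rows, c))
        X = pd.concat(parts, axis=1)
        for a, b in self.interactions:
            A = self._encode(rows, a, group=group, period=period)
            B = self._encode(rows, b, group=group, period=period)
            for ca in A.columns:
                for cb in B.columns:
                    X[f"{ca}:{cb}"] = A[ca] * B[cb]
        return X


@dataclass
class FitPart:
    """One fitted model part: coefficients, covariance, likelihood."""

    params: pd.Series
    cov_params: pd.DataFrame
    bse: pd.Series
    llf: float
    kind: str  # logit | truncated_negbin | truncated_poisson | gamma
    alpha: float | None = None
    shape: float | None = None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )

    def term_ratio(self, term: str, level: float = 0.95) -> tuple:
        """exp(coefficient) with its Wald interval (OR / RR / cost ratio)."""
        ci = self.conf_int(level).loc[term]
        return (
            float(np.exp(self.params[term])),
            float(np.exp(ci["low"])),
            float(np.exp(ci["high"])),
        )


@dataclass
class TwoPartFit:
    spec: ModelSpec
    design: Design
    part1: FitPart
    part2: FitPart
    family_used: str
    n_rows: int
    n_nonzero: int
    dispersion_ratio: float | None = None

    @property
    def odds_ratio(self):
        return self.part1.term_ratio(GROUP_COL)

    @property
    def rate_ratio(self):
        return self.part2.term_ratio(GROUP_COL)


def _drop_unidentified(X: pd.DataFrame, context: str) -> pd.DataFrame:
    """Drop dummy/interaction columns that are constant in a fitted subset.

    A categorical level can be present in the cohort but absent among the
    non-zero rows the second part conditions on; its coefficient is then
    unidentified.  The level is collapsed into the reference for that fit
    (with a warning) rather than aborting.
    """
    arr = X.to_numpy(float)
    dropped = [
        c
        for j, c in enumerate(X.columns)
        if ("[" in c or ":" in c) and arr[:, j].min() == arr[:, j].max()
    ]
    if dropped:
        warnings.warn(
            f"collapsing unidentified term(s) {dropped} into the reference "
            f"({context})",
            RuntimeWarning,
            stacklevel=3,
        )
        return X.drop(columns=dropped)
    return X


def _offset(rows: pd.DataFrame) -> np.ndarray:
    days = rows["follow_up_days"].to_numpy(float)
    if np.any(days <= 0):
        raise ValueError("non-positive follow-up; exclude zero-length rows upstream")
    return np.log(days / DAYS_PER_YEAR)


def fit_binomial_part(
    rows: pd.DataFrame, spec: ModelSpec, design: Design | None = None
) -> FitPart:
    """Logistic regression of the any-use indicator on the adjustment set."""
    design = Design(rows, spec.covariates) if design is None else design
    y = (rows[spec.outcome] > 0).astype(float)
    if y.nunique() < 2:
        raise ValueError(
            "first-part outcome indicator is constant "
            f"(all {'non-zero' if y.iloc[0] else 'zero'})"
        )
    X = design.matrix(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except (sm.tools.sm_exceptions.PerfectSeparationWarning, Exception) as err:
            if "Separation" in type(err).__name__ or "separat" in str(err).lower():
                raise ValueError(f"perfect separation in first part: {err}") from err
            raise
    bad = ~np.isfinite(res.bse) | (np.abs(res.params) > 30)
    if bad.any():
        raise ValueError(
            "perfect separation in first part; offending term(s): "
            f"{list(res.params.index[bad])}"
        )
    return FitPart(
        params=res.params,
        cov_params=res.cov_params(),
        bse=res.bse,
        llf=float(res.llf),
        kind="logit",
    )


def overdispersion_check(
    rows: pd.DataFrame, spec: ModelSpec, design: Design | None = None
) -> tuple[float, str]:
    """Poisson deviance/df ratio on the non-zero rows; choose the family.

    A ratio above the threshold (default exactly 1.0) selects the negative
    binomial; otherwise Poisson.  A configured ``family_override`` wins.
    """
    pos = rows[rows[spec.outcome] > 0]
    design = Design(rows, spec.covariates) if design is None else design
    X = _drop_unidentified(design.matrix(pos), "overdispersion check")
    res = sm.GLM(
        pos[spec.outcome].to_numpy(float),
        X,
        family=sm.families.Poisson(),
        offset=_offset(pos),
    ).fit()
    if res.df_resid <= 0:
        raise ValueError("residual degrees of freedom <= 0")
    ratio = float(res.deviance / res.df_resid)
    if spec.family_override is not None:
        return ratio, spec.family_override
    family = "negbin" if ratio > spec.dispersion_threshold else "poisson"
    return ratio, family


def fit_truncated_count_part(
    rows: pd.DataFrame,
    spec: ModelSpec,
    family: str = "negbin",
    design: Design | None = None,
) -> FitPart:
    """Zero-truncated count MLE on the rows with a positive outcome."""
    pos = rows[rows[spec.outcome] > 0]
    design = Design(rows, spec.covariates) if design is None else design
    X = _drop_unidentified(design.matrix(pos), "truncated count part")
    model = TruncatedCountModel(
        pos[spec.outcome].to_numpy(float), X, offset=_offset(pos), family=family
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit()
    boundary = any("zero boundary" in str(w.message) for w in caught)
    if boundary and family == "negbin":
        warnings.warn(
            "dispersion at the zero boundary; refitting as truncated Poisson",
            RuntimeWarning,
            stacklevel=2,
        )
        model = TruncatedCountModel(
            pos[spec.outcome].to_numpy(float), X, offset=_offset(pos), family="poisson"
        )
        res = model.fit()
    kind = "truncated_negbin" if res.family == "negbin" else "truncated_poisson"
    return FitPart(
        params=res.params,
        cov_params=res.cov_params,
        bse=res.bse,
        llf=res.llf,
        kind=kind,
        alpha=res.alpha,
        converged=res.converged,
        diagnostics={"n_iter": res.n_iter, "grad_norm": res.grad_norm,
                     "alpha_se": res.alpha_se},
    )


def fit_gamma_cost_part(
    rows: pd.DataFrame, spec: ModelSpec, design: Design | None = None
) -> FitPart:
    """Log-link Gamma GLM on the rows with positive cost."""
    pos = rows[rows[spec.outcome] > 0]
    if (pos[spec.outcome] <= 0).any() or len(pos) < len(
        rows[rows[spec.outcome] != 0]
    ):
        raise ValueError("cost part requires strictly positive costs upstream")
    design = Design(rows, spec.covariates) if design is None else design
    X = _drop_unidentified(design.matrix(pos), "cost part")
    res = sm.GLM(
        pos[spec.outcome].to_numpy(float),
        X,
        family=sm.families.Gamma(link=sm.families.links.Log()),
        offset=_offset(pos),
    ).fit(scale="X2")
    shape = 1.0 / float(res.scale)  # Gamma shape = 1 / dispersion
    return FitPart(
        params=res.params,
        cov_params=res.cov_params(),
        bse=res.bse,
        llf=float(res.llf),
        kind="gamma",
        shape=shape,
    )


def fit_two_part(
    rows: pd.DataFrame, spec: ModelSpec, design: Design | None = None
) -> TwoPartFit:
    """Fit both parts of the hurdle model for one outcome column."""
    design = Design(rows, spec.covariates) if design is None else design
    part1 = fit_binomial_part(rows, spec, design)
    if spec.is_cost:
        part2 = fit_gamma_cost_part(rows, spec, design)
        family, ratio = "gamma", None
    else:
        ratio, family = overdispersion_check(rows, spec, design)
        part2 = fit_truncated_count_part(rows, spec, family, design)
    return TwoPartFit(
        spec=spec,
        design=design,
        part1=part1,
        part2=part2,
        family_used=family,
        n_rows=len(rows),
        n_nonzero=int((rows[spec.outcome] > 0).sum()),
        dispersion_ratio=ratio,
    )


def estimates_frame(fit: TwoPartFit, level: float = 0.95) -> pd.DataFrame:
    """Tidy (part, term, estimate, se, ci_low, ci_high, scale) table."""
    frames = []
    for name, part, scale in (
        ("part1", fit.part1, "log-odds"),
        ("part2", fit.part2, "log-rate"),
    ):
        ci = part.conf_int(level)
        frames.append(
            pd.DataFrame(
                {
                    "part": name,
                    "term": part.params.index,
                    "estimate": part.params.values,
                    "se": part.bse.values,
                    "ci_low": ci["low"].values,
                    "ci_high": ci["high"].values,
                    "scale": scale,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["outcome"] = fit.spec.outcome
    out.attrs["family_used"] = fit.family_used
    return out
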