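"""End-to-end orchestration: simulate or read inputs, build the cohort,
construct outcomes, fit the two-part models, predict, and run the
historical (DID) and sensitivity analyses, writing every intermediate.

Re-running with an identical configuration and inputs reproduces identical
outputs: all randomness (simulation, matching tie-breaks, bootstraps)
derives from the configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import apply_eligibility, compute_follow_up_table, match_exposed
from .descriptives import stratified_analysis, table_one
from .did import build_did_rows, check_common_trend, fit_did
from .io import PipelineConfig, read_inputs, write_table, write_unit_costs
from .outcomes import build_analysis_rows
from .predict import predict_average, predict_with_ci
from .synthetic import (
    SimulationParams,
    default_unit_costs,
    generate_events,
    generate_population,
)
from .twopart import ModelSpec, estimates_frame, fit_two_part

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_inputs"]


_STREAM_IDS = {"contemporary": 1, "historical": 2, "matching": 3}


def _rng(config_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config_seed, _STREAM_IDS[stream]])
    )


def simulate_inputs(config: PipelineConfig):
    """Generate the patient table, ground truth and unit costs."""
    overrides = dict(config.simulation)
    overrides.setdefault("seed", config.seed)
    params = SimulationParams(**overrides)
    patients, truth = generate_population(params)
    return patients, truth, default_unit_costs(), params


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a bundle of result tables and paths."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"output_dir": str(out_dir)}
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(config.__dict__, default=str)),
        "stages": {},
    }
    stage = "setup"
    try:
        t0 = time.time()
        stage = "inputs"
        if config.simulate:
            patients, truth, unit_costs, params = simulate_inputs(config)
            write_table(patients, out_dir / "patients.csv")
            write_table(truth.frame, out_dir / "ground_truth.csv")
            write_unit_costs(unit_costs, out_dir / "unit_costs.csv")
            bundle["ground_truth"] = truth
            events_given = None
        else:
            patients, events_given, unit_costs, rejects = read_inputs(
                {
                    "patients": config.patients_path,
                    "events": config.events_path,
                    "unit_costs": config.unit_costs_path,
                }
            )
            params = None
            if len(rejects):
                write_table(rejects, out_dir / "rejected_events.csv")
        bundle["patients"] = patients
        bundle["unit_costs"] = unit_costs

        stage = "eligibility"
        eligible, exclusions = apply_eligibility(
            patients,
            study_start=pd.Timestamp(config.study_start),
            min_registration_days=config.min_registration_days,
        )
        log["stages"]["eligibility"] = exclusions

        stage = "matching"
        matched = match_exposed(
            eligible,
            ratio=config.matching_ratio,
            match_vars=config.match_vars,
            seed=config.seed,
        )
        write_table(matched, out_dir / "matched_sets.csv")
        bundle["matched_sets"] = matched
        log["stages"]["matching"] = {
            "n_sets": int(matched["set_id"].nunique()),
            "n_comparators": len(matched),
            "n_unmatched_exposed": matched.attrs.get("n_unmatched_exposed", 0),
        }

        stage = "follow_up"
        follow_ups = compute_follow_up_table(
            matched,
            patients,
            window_days=config.outcome_window_days,
            admin_end=pd.Timestamp(config.admin_end),
        )
        write_table(follow_ups, out_dir / "follow_up.csv")
        usable = follow_ups[~follow_ups["zero_length"]]
        bundle["follow_ups"] = usable

        stage = "events"
        if config.simulate:
            # one window per member role: a later-diagnosed comparator's
            # spell (censored at diagnosis) and their own exposed follow-up
            # are disjoint windows with role-specific rates
            windows = usable.rename(columns={"index_date": "start"})[
                ["patient_id", "group", "start", "end"]
            ].copy()
            windows["exposed"] = windows.pop("group") == "exposed"
            ev_cont = generate_events(
                patients, windows, params, "contemporary",
                rng=_rng(config.seed, "contemporary"),
            )
            hist_members = usable.drop_duplicates("patient_id").merge(
                patients[["patient_id", "registration_start"]], on="patient_id"
            )
            hist_members = hist_members[
                hist_members["registration_start"]
                <= pd.Timestamp(config.historical_start)
            ]
            hist_windows = pd.DataFrame(
                {
                    "patient_id": hist_members["patient_id"],
                    "start": pd.Timestamp(config.historical_start),
                    "end": pd.Timestamp(config.historical_end),
                }
            )
            ev_hist = generate_events(
                patients, hist_windows, params, "historical",
                rng=_rng(config.seed, "historical"),
            )
            events = pd.concat([ev_hist, ev_cont], ignore_index=True)
            write_table(events, out_dir / "events.csv")
        else:
            events = events_given
        bundle["events"] = events

        stage = "analysis_rows"
        rows = build_analysis_rows(
            matched, usable, events, patients, unit_costs, "contemporary"
        )
        write_table(rows, out_dir / "analysis_rows.csv")
        bundle["analysis_rows"] = rows

        stage = "two_part_models"
        estimates, predictions = [], []
        bundle["fits"] = {}
        for outcome in config.outcomes:
            spec = ModelSpec(
                outcome=outcome,
                covariates=config.covariates,
                dispersion_threshold=config.dispersion_threshold,
            )
            fit = fit_two_part(rows, spec)
            bundle["fits"][outcome] = fit
            est = estimates_frame(fit)
            est.insert(0, "outcome", outcome)
            est["family_used"] = fit.family_used
            estimates.append(est)
            if config.bootstrap_reps:
                preds = predict_with_ci(
                    rows, spec, n_reps=config.bootstrap_reps, seed=config.seed
                )
                for p in preds:
                    predictions.append(
                        {
                            "outcome": outcome,
                            "group": p.group,
                            "mean": p.predicted_mean,
                            "ci_low": p.ci_low,
                            "ci_high": p.ci_high,
                        }
                    )
            else:
                for g in ("exposed", "comparator"):
                    predictions.append(
                        {
                            "outcome": outcome,
                            "group": g,
                            "mean": predict_average(fit, rows, g),
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                        }
                    )
        est_table = pd.concat(estimates, ignore_index=True)
        write_table(est_table, out_dir / "estimates.csv")
        pred_table = pd.DataFrame(predictions)
        write_table(pred_table, out_dir / "predictions.csv")
        bundle["estimates"] = est_table
        bundle["predictions"] = pred_table

        if config.run_did:
            stage = "did"
            did_rows = build_did_rows(
                matched, events, patients, unit_costs, follow_ups=usable
            )
            write_table(did_rows, out_dir / "did_rows.csv")
            did = fit_did(
                did_rows,
                covariates=config.covariates,
                n_bootstrap=config.bootstrap_reps,
                seed=config.seed,
            )
            did_table = pd.DataFrame(
                [
                    {"group": g, "period": p, "predicted_mean": m}
                    for (g, p), m in did.predicted_means.items()
                ]
            )
            did_table.attrs["did_estimate"] = did.did_estimate
            write_table(did_table, out_dir / "did_predicted_means.csv")
            with open(out_dir / "did_result.json", "w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "did_estimate": did.did_estimate,
                        "ci_low": None if np.isnan(did.ci_low) else did.ci_low,
                        "ci_high": None if np.isnan(did.ci_high) else did.ci_high,
                        "within_group_differences": did.within_group_differences,
                        "interaction_part1": did.interaction_part1,
                        "interaction_part2": did.interaction_part2,
                    },
                    fh,
                    indent=2,
                )
            members = usable.drop_duplicates("patient_id").merge(
                patients, on="patient_id"
            )
            trend = check_common_trend(
                events,
                members,
                bins=4,
                window=(config.historical_start, config.historical_end),
                plot_path=out_dir / "common_trend.png",
            )
            write_table(trend, out_dir / "common_trend.csv")
            bundle["did"] = did
            bundle["common_trend"] = trend

        if config.run_descriptives:
            stage = "descriptives"
            members = usable[["patient_id", "group"]].drop_duplicates(
                "patient_id"
            ).merge(patients, on="patient_id")
            members["age_category"] = pd.cut(
                members["age"],
                bins=[18, 30, 40, 50, 60, 70, 120],
                labels=["18-29", "30-39", "40-49", "50-59", "60-69", "70+"],
                right=False,
            ).astype(str)
            tab1 = table_one(members)
            write_table(tab1, out_dir / "table_one.csv")
            bundle["table_one"] = tab1

        for var in config.stratify_by:
            stage = f"stratified[{var}]"
            spec = ModelSpec(outcome="total_visits", covariates=config.covariates)
            strata = stratified_analysis(rows, spec, var)
            strat_table = pd.DataFrame(
                [
                    {
                        "variable": s.variable,
                        "level": s.level,
                        "odds_ratio": s.odds_ratio,
                        "or_low": s.or_ci[0],
                        "or_high": s.or_ci[1],
                        "rate_ratio": s.rate_ratio,
                        "rr_low": s.rr_ci[0],
                        "rr_high": s.rr_ci[1],
                        "lrt_p_part1": s.lrt_p_part1,
                        "lrt_p_part2": s.lrt_p_part2,
                        "lrt_df": s.lrt_df,
                    }
                    for s in strata
                ]
            )
            write_table(strat_table, out_dir / f"stratified_{var}.csv")
            bundle[f"stratified_{var}"] = strat_table

        log["runtime_seconds"] = round(time.time() - t0, 2)
    except Exception as err:
        log["failed_stage"] = stage
        log["error"] = str(err)
        with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)
    bundle["run_log"] = log
    return bundle
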