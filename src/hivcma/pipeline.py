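"""End-to-end orchestration: synth -> eligibility -> CMA -> analyses -> report.

``run_pipeline`` executes the whole analysis on a generated (or loaded)
cohort and writes a report bundle of delimited-text tables with a JSON
manifest: cohort characteristics by mental-health status, risk-ratio
tables for non-adherence and viral non-suppression (with CMA mediation),
trajectory-group summary, marginal-prediction tables, and the CMA
validation (AUC) table.  Re-running with an identical config produces an
identical bundle.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from hivcma import adherence, claims_io, models, synth, trajectories, validation

log = logging.getLogger("hivcma.pipeline")


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Column percentage, rounded half-away-from-zero."""
    if denominator == 0:
        return float("nan")
    x = 100.0 * numerator / denominator
    q = 10.0**decimals
    return np.sign(x) * np.floor(abs(x) * q + 0.5) / q


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    n_patients: int = 2000
    seed: int = 42
    input_dir: str | None = None  # read tables instead of generating
    out_dir: str = "results/pipeline"
    non_adherence_pct: int = 80
    vns_threshold: float = 400.0
    diagnosis_definition: str = "single"  # or "repeat"
    k_range: tuple = (2, 6)
    n_starts: int = 5
    n_boot: int = 200
    auc_windows: tuple = (1, 3, 6, 12)
    generator_overrides: dict = field(default_factory=dict)


def summarize_table1(cohort: pd.DataFrame, timeline: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics by mental-health status at end of follow-up.

    One row per characteristic level with counts and column percentages
    (one decimal, half-away-from-zero) for the no-diagnosis, diagnosis
    and total columns; follow-up time reported as median (IQR) rows.
    """
    flags = claims_io.exposure_flags(timeline, cohort["patient_id"], cohort["followup_end"])
    df = pd.concat([cohort.reset_index(drop=True), flags.reset_index(drop=True)], axis=1)
    df["age_group"] = models.age_to_group(
        (df["baseline"] - df["birth_date"]).dt.days / 365.25
    )
    groups = {"no_mh": df[~df["mh_any"]], "mh": df[df["mh_any"]], "total": df}
    rows = []

    def block(name, level, counts):
        row = {"block": name, "level": level}
        for col, sub in groups.items():
            row[f"{col}_n"] = counts[col]
            row[f"{col}_pct"] = percent(counts[col], len(sub))
        rows.append(row)

    for ag in models.AGE_GROUPS:
        block("age_group", ag, {c: int((g["age_group"] == ag).sum()) for c, g in groups.items()})
    for s in ("male", "female"):
        block("sex", s, {c: int((g["sex"] == s).sum()) for c, g in groups.items()})
    for cat in claims_io.MH_CATEGORIES:
        block("mh_category", cat, {c: int(g[f"mh_{cat}"].sum()) for c, g in groups.items()})
    for col, sub in groups.items():
        fy = sub["followup_days"] / 365.25
        rows.append({
            "block": "followup_years", "level": f"median_iqr_{col}",
            f"{col}_n": len(sub),
            f"{col}_pct": float("nan"),
            "median": round(float(fy.median()), 1) if len(fy) else float("nan"),
            "iqr_low": round(float(fy.quantile(0.25)), 1) if len(fy) else float("nan"),
            "iqr_high": round(float(fy.quantile(0.75)), 1) if len(fy) else float("nan"),
        })
    n_tot = {c: len(g) for c, g in groups.items()}
    rows.insert(0, {"block": "n", "level": "patients",
                    "no_mh_n": n_tot["no_mh"], "no_mh_pct": percent(n_tot["no_mh"], n_tot["total"]),
                    "mh_n": n_tot["mh"], "mh_pct": percent(n_tot["mh"], n_tot["total"]),
                    "total_n": n_tot["total"], "total_pct": 100.0})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the bundle as a dict of DataFrames (plus the resolved
    config); any stage failure raises with the stage name.
    """
    out: dict = {"config": config}
    stage = "generate"
    try:
        if config.input_dir:
            tables = claims_io.read_tables(config.input_dir)
            truth = None
        else:
            gen = synth.study_scenario(
                n_patients=config.n_patients, seed=config.seed, **config.generator_overrides
            )
            tables, truth = synth.generate_cohort(gen)
        claims_io.validate_tables(tables)
        log.info("stage=%s patients=%d pharmacy=%d", stage, len(tables.patients), len(tables.pharmacy))

        stage = "eligibility"
        elig = claims_io.apply_eligibility(tables)
        if elig.empty:
            raise RuntimeError("empty cohort after eligibility filtering")
        for step, excl, remaining in elig.flow:
            log.info("stage=%s step=%r excluded=%d remaining=%d", stage, step, excl, remaining)
        out["exclusion_flow"] = pd.DataFrame(elig.flow, columns=["step", "n_excluded", "n_remaining"])

        stage = "diagnosis_timeline"
        timeline = claims_io.build_diagnosis_timeline(
            tables.diagnoses, require_repeat=(config.diagnosis_definition == "repeat")
        )

        stage = "table1"
        out["table1"] = summarize_table1(elig.cohort, timeline)

        stage = "cma"
        ddd = claims_io.load_ddd_table()
        cohort = elig.cohort
        adh_cohort = cohort[cohort["patient_id"].isin(elig.analysis_ids["adherence"])]
        cma3 = adherence.cohort_cma(tables, cohort, 3, ddd=ddd)
        cma12 = adherence.cohort_cma(tables, adh_cohort, 12, ddd=ddd)
        out["cma_12m"] = adherence.flag_non_adherence(cma12, config.non_adherence_pct)
        log.info("stage=%s windows_3m=%d windows_12m=%d", stage, len(cma3), len(cma12))

        stage = "trajectories"
        trj_ids = elig.analysis_ids["trajectory"]
        idx, mat, _ = trajectories.build_trajectory_matrix(
            cma3[cma3["patient_id"].isin(trj_ids)]
        )
        model = None
        if len(mat) >= 50:
            full = trajectories.impute_trajectory(mat)
            model, crit = trajectories.select_k(
                full, range(config.k_range[0], config.k_range[1] + 1),
                n_starts=config.n_starts, seed=config.seed,
            )
            out["trajectory_criteria"] = crit
            out["trajectory_centroids"] = pd.DataFrame(
                model.centroids, columns=[f"q{j}" for j in range(model.centroids.shape[1])]
            ).assign(label=[model.labels[j] for j in range(model.k)])
            out["trajectory_assignments"] = pd.DataFrame(
                {"patient_id": idx, "cluster": model.assignments,
                 "label": [model.labels[a] for a in model.assignments]}
            )
            shares = trajectories.group_shares(model)
            out["trajectory_shares"] = pd.DataFrame(
                sorted(shares.items()), columns=["label", "share"]
            )
            if truth is not None:
                out["trajectory_truth"] = truth.patients[["patient_id", "behaviour_class"]]

        stage = "validation"
        sup_cohort = cohort[cohort["patient_id"].isin(elig.analysis_ids["suppression"])]
        daily = _daily_by_patient(tables, sup_cohort, ddd)
        if len(sup_cohort):
            out["validation"] = validation.auc_by_window(
                daily, sup_cohort, tables.labs, windows=config.auc_windows,
                vns_threshold=config.vns_threshold, n_boot=config.n_boot, seed=config.seed,
            )

        stage = "rr_nonadherence"
        pp = models.build_person_period(
            adh_cohort, cma12, timeline, threshold_pct=config.non_adherence_pct
        )
        out["person_period"] = pp
        if pp["outcome"].nunique() == 2:
            fits = {}
            for tag, adj in [("unadjusted", "none"), ("adj-demographic", "demo"),
                             ("adj-comorbidity", "comorbid")]:
                fit = _try_fit(pp, models.rr_formula(adj), tag)
                if fit is not None:
                    fits[tag] = fit
            if fits:
                out["rr_nonadherence"] = pd.concat(
                    [f.estimates.assign(model=tag) for tag, f in fits.items()],
                    ignore_index=True,
                )
            stage = "fig1_predictions"
            out["fig1_cma_by_stratum"] = _mean_cma_year2(cma12, adh_cohort, timeline)

        stage = "rr_vns"
        vns = models.build_vns_table(
            sup_cohort, daily, tables.labs, timeline, vns_threshold=config.vns_threshold
        )
        out["vns_table"] = vns
        if len(vns) and vns["outcome"].nunique() == 2:
            vfits = {}
            for tag, adj in [("unadjusted", "none"), ("adj-demographic", "demo")]:
                fit = _try_fit(vns, models.rr_formula(adj), tag)
                if fit is not None:
                    vfits[tag] = fit
            if vfits:
                out["rr_vns"] = pd.concat(
                    [f.estimates.assign(model=tag) for tag, f in vfits.items()],
                    ignore_index=True,
                )
            stage = "mediation"
            try:
                out["mediation"] = models.mediation_by_cma(vns)
            except Exception as exc:  # rare categories can defeat identification
                log.warning("mediation models not identifiable: %s", exc)
            stage = "fig3_predictions"
            if "adj-demographic" in vfits:
                out["fig3_vns_predictions"] = models.marginal_predictions(
                    vfits["adj-demographic"], vns, at_period=2
                )

        stage = "multinomial_groups"
        if model is not None and "trajectory_assignments" in out:
            grp = out["trajectory_assignments"].merge(
                cohort[["patient_id", "sex", "birth_date", "baseline"]], on="patient_id"
            )
            grp["age_group"] = models.age_to_group(
                (grp["baseline"] - grp["birth_date"]).dt.days / 365.25
            )
            base_flags = claims_io.exposure_flags(timeline, grp["patient_id"], grp["baseline"])
            grp["mh_baseline"] = base_flags["mh_any"].to_numpy().astype(int)
            grp = grp.rename(columns={"label": "group"})
            if grp["group"].nunique() >= 2 and (grp["group"] == "continuous_high").any():
                rrr, pred, _ = models.fit_multinomial_groups(grp)
                out["trajectory_rrr"] = rrr
                out["fig2_group_probabilities"] = pred
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_bundle(out, config)
    return out


def _try_fit(table, formula, tag):
    """Fit one RR model; return None (with a warning) if unidentifiable."""
    try:
        return models.fit_rr_model(table, formula, model_tag=tag)
    except Exception as exc:
        log.warning("model %s not fitted: %s", tag, exc)
        return None


def _daily_by_patient(tables, cohort, ddd) -> dict:
    """Per-day adherence arrays for every patient in a cohort frame."""
    art = tables.pharmacy[tables.pharmacy["atc_code"].map(claims_io.is_art_claim)]
    by_patient = dict(tuple(art.groupby("patient_id")))
    out = {}
    for r in cohort.itertuples(index=False):
        claims = by_patient.get(r.patient_id)
        if claims is None:
            continue
        c = claims.copy()
        c["duration_days"] = [
            adherence.claim_duration(p, claims_io.daily_dose_for(a, ddd))
            for p, a in zip(c["pills_dispensed"], c["atc_code"])
        ]
        iv = adherence.build_refill_intervals(c, r.baseline, r.followup_end)
        total = int((r.followup_end - r.baseline) / pd.Timedelta(days=1))
        out[r.patient_id] = adherence.daily_adherence(iv, total)
    return out


def _mean_cma_year2(cma12, cohort, timeline) -> pd.DataFrame:
    """Observed mean 12-month CMA in the 2nd year by age, sex and diagnosis."""
    y2 = cma12[cma12["window_index"] == 1].merge(
        cohort[["patient_id", "sex", "birth_date", "baseline"]], on="patient_id"
    )
    if y2.empty:
        return pd.DataFrame()
    y2["age_group"] = models.age_to_group((y2["window_start"] - y2["birth_date"]).dt.days / 365.25)
    flags = claims_io.exposure_flags(timeline, y2["patient_id"], y2["window_start"])
    y2["mh_any"] = flags["mh_any"].to_numpy()
    agg = (
        y2.groupby(["age_group", "sex", "mh_any"], observed=True)["cma_value"]
        .agg(["mean", "std", "count"]).reset_index()
    )
    se = agg["std"] / np.sqrt(agg["count"].clip(lower=1))
    agg["ci_low"] = agg["mean"] - 1.96 * se
    agg["ci_high"] = agg["mean"] + 1.96 * se
    return agg


def _write_bundle(out: dict, config: RunConfig) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {"config": asdict(config), "tables": []}
    for name, obj in out.items():
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(config.out_dir, f"{name}.csv")
            obj.to_csv(path, index=False, float_format="%.10g")
            manifest["tables"].append(f"{name}.csv")
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("bundle written to %s (%d tables)", config.out_dir, len(manifest["tables"]))
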