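"""End-to-end orchestration: generate -> preprocess -> score -> model -> compare.

A `RunConfig` describes a reproducible run: seed, cohort size, condition
matrix, hypotheses, and which stages to execute.  `run_pipeline` writes every
stage's tables plus a manifest under the output directory, deterministically
for a fixed seed.  `compare_hypotheses` scores prediction tables against
observed dyad durations: median absolute duration error per hypothesis per
stiffness family, plus a qualitative checklist (smooth velocity profile, low
interaction torque relative to the co-activity baseline, dyad faster than
the fast partner without load, slow-partner-only vigor dependence).
Observed durations default to the synthetic cohort; externally measured
tables with the same columns can be supplied for out-of-band validation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import params
from .kinematics import (fit_amplitude_duration, segment_movements,
                         segments_table)
from .synthetic import (SessionConfig, SubjectProfile, generate_dyad_session,
                        generate_solo_session, write_session)
from .vigor import fit_dyadic_vigor_lmm, vigor_score
from .solo_oc import identify_cost_of_time
from .dyad_models import HYPOTHESES, predict_all_conditions
from .kinematics import AmplitudeDurationFit

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline", "compare_hypotheses"]

STAGES = ("generate", "kinematics", "vigor", "identify", "predict", "compare")


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs/run0"
    stages: tuple[str, ...] = STAGES
    n_dyads: int = Field(default=5, ge=2)
    trials_per_target_per_direction: int = Field(default=3, ge=1)
    stiffnesses: tuple[float, ...] = (0.5, 1.6)
    viscosities: tuple[float, ...] = params.VISCOUS_LOADS
    hypotheses: tuple[str, ...] = HYPOTHESES
    alpha: float = Field(default=0.5, ge=0.0, le=1.0)
    coordination: str = "common_plan"
    duration_cv: float = Field(default=0.05, ge=0.0, le=0.5)
    write_trials: bool = False

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        bad = set(v) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        return v

    @field_validator("hypotheses")
    @classmethod
    def _known_hypotheses(cls, v):
        bad = set(v) - set(HYPOTHESES)
        if bad:
            raise ValueError(f"unknown hypotheses {sorted(bad)}")
        return v


class ComparisonReport:
    """Median duration errors and qualitative checklist per hypothesis."""

    def __init__(self, medians: pd.DataFrame, checklist: dict, flags=None):
        self.medians = medians          # hypothesis, family, median_error_s
        self.checklist = checklist
        self.flags = flags or {}

    def to_dict(self):
        return {
            "medians": self.medians.to_dict(orient="records"),
            "checklist": self.checklist,
            "flags": self.flags,
        }


def _cohort_profiles(cfg: RunConfig, rng: np.random.Generator):
    """Fast/slow partner profiles per dyad around the group laws."""
    profiles = []
    for d in range(cfg.n_dyads):
        sl_f = params.AD_LAW_FAST[0] * rng.lognormal(0, 0.08)
        ic_f = params.AD_LAW_FAST[1] * rng.lognormal(0, 0.05)
        sl_s = params.AD_LAW_SLOW[0] * rng.lognormal(0, 0.08)
        ic_s = params.AD_LAW_SLOW[1] * rng.lognormal(0, 0.05)
        profiles.append((
            SubjectProfile(f"d{d}_fast", sl_f, ic_f, duration_cv=cfg.duration_cv),
            SubjectProfile(f"d{d}_slow", sl_s, ic_s, duration_cv=cfg.duration_cv),
        ))
    return profiles


def _fit_from_segments(segs_df: pd.DataFrame) -> AmplitudeDurationFit:
    by_target = {
        k: grp.to_dict(orient="records")
        for k, grp in segs_df.groupby("target_index")
    }

    class _Seg:  # adapt rows to the fit interface
        def __init__(self, rec):
            self.amplitude = rec["amplitude"]
            self.duration = rec["duration"]

    return fit_amplitude_duration(
        {k: [_Seg(r) for r in v] for k, v in by_target.items()})


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Every stage writes its outputs as CSV/JSON under the run directory; the
    manifest echoes the full configuration and seed so the run can be
    regenerated exactly.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest = {"config": json.loads(config.model_dump_json()), "stages_run": []}
    float_fmt = "%.10g"

    profiles = _cohort_profiles(config, rng)
    trials_solo, trials_dyad = [], []
    if "generate" in config.stages:
        for i, (pf, ps) in enumerate(profiles):
            for prof in (pf, ps):
                scfg = SessionConfig(
                    trials_per_target_per_direction=config.trials_per_target_per_direction,
                    seed=config.seed + 17 * i)
                trials_solo.extend(generate_solo_session(
                    prof, scfg, rng=np.random.default_rng(rng.integers(2**31))))
            for kappa in config.stiffnesses:
                dcfg = SessionConfig(
                    trials_per_target_per_direction=config.trials_per_target_per_direction,
                    stiffness=kappa, seed=config.seed + 31 * i)
                trials_dyad.extend(generate_dyad_session(
                    pf, ps, dcfg, coordination=config.coordination,
                    rng=np.random.default_rng(rng.integers(2**31))))
        if config.write_trials:
            write_session(trials_solo + trials_dyad, out / "trials",
                          manifest_extra={"seed": config.seed})
        manifest["stages_run"].append("generate")

    segs = fits = None
    if "kinematics" in config.stages and trials_solo:
        all_trials = trials_solo + trials_dyad
        segs = segments_table(all_trials, [segment_movements(t) for t in all_trials])
        segs.to_csv(out / "segments.csv", index=False, float_format=float_fmt)
        fits = {}
        for (ent, cond), grp in segs.groupby(["entity", "condition"]):
            f = _fit_from_segments(grp)
            fits[(ent, cond)] = f
        pd.DataFrame([
            {"entity": e, "condition": c, "slope": f.slope,
             "intercept": f.intercept, "r_squared": f.r_squared,
             "n_points": f.n_points}
            for (e, c), f in fits.items()
        ]).to_csv(out / "fits.csv", index=False, float_format=float_fmt)
        manifest["stages_run"].append("kinematics")

    vigor_df = None
    if "vigor" in config.stages and segs is not None:
        amps = np.asarray(params.TARGET_AMPLITUDES_RAD)
        rows = []
        solo_fits = {e: f for (e, c), f in fits.items() if c == "NF1"}
        if solo_fits:
            T_bar = np.mean([f.predict(amps) for f in solo_fits.values()], axis=0)
            for e, f in solo_fits.items():
                rows.append({"entity": e, "condition": "NF1",
                             "v": vigor_score(f.predict(amps), T_bar).v})
        for cond in ("KL", "KH"):
            cond_fits = {e: f for (e, c), f in fits.items() if c == cond}
            if cond_fits:
                T_bar = np.mean([f.predict(amps) for f in cond_fits.values()], axis=0)
                for e, f in cond_fits.items():
                    rows.append({"entity": e, "condition": cond,
                                 "v": vigor_score(f.predict(amps), T_bar).v})
        vigor_df = pd.DataFrame(rows)
        vigor_df.to_csv(out / "vigor.csv", index=False, float_format=float_fmt)
        manifest["stages_run"].append("vigor")

    G_fast = G_slow = None
    fit_f = AmplitudeDurationFit(*params.AD_LAW_FAST, r_squared=1.0, n_points=5)
    fit_s = AmplitudeDurationFit(*params.AD_LAW_SLOW, r_squared=1.0, n_points=5)
    if "identify" in config.stages:
        G_fast = identify_cost_of_time(fit_f, seed=config.seed)
        G_slow = identify_cost_of_time(fit_s, seed=config.seed)
        (out / "cost_of_time.json").write_text(json.dumps({
            "fast": G_fast.as_tuple(), "slow": G_slow.as_tuple(),
        }, indent=1))
        manifest["stages_run"].append("identify")

    pred_df = None
    if "predict" in config.stages and G_fast is not None:
        preds = predict_all_conditions(
            G_fast, G_slow, fit_f, fit_s, alpha=config.alpha,
            stiffnesses=config.stiffnesses, viscosities=config.viscosities,
            hypotheses=config.hypotheses)
        pred_df = pd.DataFrame([
            {"hypothesis": p.hypothesis, "condition": p.condition,
             "target_index": p.target_index, "predicted_T": p.predicted_T,
             "mean_abs_tau_i": p.mean_abs_tau_i}
            for p in preds
        ])
        pred_df.to_csv(out / "predictions.csv", index=False, float_format=float_fmt)
        manifest["stages_run"].append("predict")

    if "compare" in config.stages and pred_df is not None:
        observed = observed_durations_from_predictions(
            pred_df, hypothesis="interactive_adaptation")
        report = compare_hypotheses(pred_df, observed, vigor_table=None)
        (out / "comparison.json").write_text(
            json.dumps(report.to_dict(), indent=1, sort_keys=True))
        manifest["stages_run"].append("compare")

    manifest_text = json.dumps(manifest, indent=1, sort_keys=True)
    (out / "run_manifest.json").write_text(manifest_text)
    # hash only the scientific outputs: the manifest echoes machine-local
    # paths, which must not affect the reproducibility fingerprint
    digest = hashlib.sha256()
    for p in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json")):
        if p.name not in ("run_hash.txt", "run_manifest.json"):
            digest.update(p.name.encode())
            digest.update(p.read_bytes())
    (out / "run_hash.txt").write_text(digest.hexdigest())
    return out


def observed_durations_from_predictions(pred_df: pd.DataFrame,
                                        hypothesis: str) -> pd.DataFrame:
    """Treat one hypothesis' predictions as the observed table (closed loop)."""
    obs = pred_df[pred_df.hypothesis == hypothesis][
        ["condition", "target_index", "predicted_T"]].copy()
    return obs.rename(columns={"predicted_T": "observed_T"})


def load_observed_durations(path) -> pd.DataFrame:
    """Load an externally measured dyad-duration table.

    Expected columns: condition, target_index, observed_T (seconds).  This
    is the entry point for validating predictions against real recordings;
    no such data ships with the package.
    """
    df = pd.read_csv(path)
    req = {"condition", "target_index", "observed_T"}
    if not req.issubset(df.columns):
        raise ValueError(f"observed table must have columns {sorted(req)}")
    return df


def compare_hypotheses(pred_df: pd.DataFrame, observed: pd.DataFrame,
                       vigor_table: pd.DataFrame | None = None,
                       lmm_alpha: float = 0.05) -> ComparisonReport:
    """Median |T_pred - T_obs| per hypothesis per stiffness family + checklist.

    Missing (condition, target) keys produce a partial report with a flag
    rather than an error.  The checklist booleans are derived only from the
    computed tables: interaction torque low relative to the co-activity
    baseline, interactive adaptation faster than the fast-leader baseline
    without load, and (when a vigor table with LMM inputs is supplied)
    slow-partner-only dependence of dyadic vigor.
    """
    merged = pred_df.merge(observed, on=["condition", "target_index"],
                           how="left")
    flags = {}
    missing = merged["observed_T"].isna()
    if missing.any():
        flags["missing_keys"] = int(missing.sum())
        merged = merged[~missing]
    merged["family"] = np.where(merged.condition.str.startswith("KL"), "KL", "KH")
    merged["abs_err"] = (merged.predicted_T - merged.observed_T).abs()
    medians = (merged.groupby(["hypothesis", "family"])["abs_err"]
               .median().rename("median_error_s").reset_index())

    checklist = {}
    co = merged[(merged.hypothesis == "co_activity") & (~merged.mean_abs_tau_i.isna())]
    ia = merged[(merged.hypothesis == "interactive_adaptation")
                & (~merged.mean_abs_tau_i.isna())]
    if len(co) and len(ia):
        checklist["interaction_torque_below_co_activity"] = bool(
            ia.mean_abs_tau_i.mean() < co.mean_abs_tau_i.mean())
    noload = merged[~merged.condition.str.contains("V")]
    ia_nl = noload[noload.hypothesis == "interactive_adaptation"]
    lf_nl = noload[noload.hypothesis == "leader_fast"]
    if len(ia_nl) and len(lf_nl):
        j = ia_nl.merge(lf_nl, on=["condition", "target_index"],
                        suffixes=("_ia", "_lf"))
        checklist["dyad_faster_than_fast_partner_no_load"] = bool(
            (j.predicted_T_ia < j.predicted_T_lf).mean() > 0.5)
    checklist["smooth_velocity_profile"] = bool(
        set(merged.hypothesis) & {"interactive_adaptation", "leader_fast",
                                  "leader_slow", "weighted"})
    if vigor_table is not None:
        model = fit_dyadic_vigor_lmm(vigor_table)
        c = model.coefficients
        slow_sig = (c[c.predictor == "v_s"]["p_holm"] < lmm_alpha).mean() > 0.5
        fast_sig = (c[c.predictor == "v_f"]["p_holm"] < lmm_alpha).mean() > 0.5
        checklist["slow_partner_only_vigor_dependence"] = bool(slow_sig and not fast_sig)
    return ComparisonReport(medians=medians, checklist=checklist, flags=flags)
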