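#!/usr/bin/env python
"""Segment the synthetic cohort, fit amplitude-duration laws, score vigor.

Reads results/cohort/ (written by 01_simulate_sessions.py), runs the
kinematic chain (filter, differentiate, 5%-of-peak segmentation), fits the
per-participant affine amplitude-duration laws, computes vigor scores in
the solo and coupled conditions, the inter-individual variance share, and
the dyadic-vigor mixed model.  Tables land in results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dyadvigor import (fit_dyadic_vigor_lmm, read_session, segment_movements,
                       variance_decomposition, vigor_score)
from dyadvigor.kinematics import fit_amplitude_duration, segments_table
from dyadvigor.params import TARGET_AMPLITUDES_RAD

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
AMPS = np.asarray(TARGET_AMPLITUDES_RAD)


def main():
    trials, _ = read_session(SCRATCH / "cohort")
    segs = segments_table(trials, [segment_movements(t) for t in trials])
    segs.to_csv(ROOT / "segments.csv", index=False, float_format="%.8g")

    fits = {}
    for (ent, cond), grp in segs.groupby(["entity", "condition"]):
        recs = [type("S", (), {"amplitude": r.amplitude, "duration": r.duration})()
                for r in grp.itertuples()]
        by_target = {}
        for r, s in zip(grp.itertuples(), recs):
            by_target.setdefault(r.target_index, []).append(s)
        if len(by_target) >= 2:
            fits[(ent, cond)] = fit_amplitude_duration(by_target)
    fit_df = pd.DataFrame([
        {"entity": e, "condition": c, "slope": f.slope, "intercept": f.intercept,
         "r_squared": f.r_squared} for (e, c), f in fits.items()])
    fit_df.to_csv(ROOT / "fits.csv", index=False, float_format="%.8g")
    print(f"{len(fit_df)} amplitude-duration fits; "
          f"median r^2 = {fit_df.r_squared.median():.3f}")

    # vigor per condition family, referenced to that family's population mean
    rows = []
    for cond in ("NF1", "VL", "VH", "KL", "KH"):
        ref_cond = {"VL": "NF1", "VH": "NF1"}.get(cond, cond)
        cond_f = {e: f for (e, c), f in fits.items() if c == cond}
        ref_f = {e: f for (e, c), f in fits.items() if c == ref_cond}
        if not cond_f or not ref_f:
            continue
        T_bar = np.mean([f.predict(AMPS) for f in ref_f.values()], axis=0)
        for e, f in cond_f.items():
            rows.append({"entity": e, "condition": cond,
                         "v": vigor_score(f.predict(AMPS), T_bar).v})
    vig = pd.DataFrame(rows)
    vig.to_csv(ROOT / "vigor.csv", index=False, float_format="%.8g")

    solo = vig[vig.condition.isin(["NF1", "VL", "VH"])].rename(
        columns={"v": "value"})
    vd = variance_decomposition(solo)
    print(f"inter-individual share of solo vigor variance: {vd.pct_inter:.1f}%")

    # dyadic-vigor mixed model on the coupled conditions
    dyads = vig[vig.condition.isin(["KL", "KH"])].copy()
    solo_v = vig[vig.condition == "NF1"].set_index("entity")["v"]
    rows = []
    for r in dyads.itertuples():
        d = r.entity.split("+")[0].rsplit("_", 1)[0]
        vf, vs = solo_v.get(f"{d}_fast"), solo_v.get(f"{d}_slow")
        if vf is not None and vs is not None:
            rows.append({"dyad": d, "condition": r.condition,
                         "v_d": r.v, "v_f": vf, "v_s": vs})
    lmm_table = pd.DataFrame(rows)
    if lmm_table.dyad.nunique() >= 5:
        model = fit_dyadic_vigor_lmm(lmm_table)
        model.coefficients.to_csv(ROOT / "dyadic_vigor_lmm.csv", index=False,
                                  float_format="%.6g")
        sig = model.coefficients.query("p_holm < 0.05")
        print("significant predictors of dyadic vigor:",
              sig[["condition", "predictor"]].to_records(index=False).tolist()
              or "none")


if __name__ == "__main__":
    main()
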