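#!/usr/bin/env python
"""Generate a synthetic cohort of solo and coupled wrist-reaching sessions.

Ten dyads (a fast and a slow partner each, drawn around the published group
amplitude-duration laws) perform solo blocks under three viscous loads and
coupled blocks at two stiffness levels.  Trials are written as per-trial
CSVs plus a session manifest under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

from dyadvigor import SessionConfig, SubjectProfile, write_session
from dyadvigor.synthetic import generate_dyad_session, generate_solo_session
from dyadvigor.params import AD_LAW_FAST, AD_LAW_SLOW, VISCOUS_LOADS

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    rng = np.random.default_rng(SEED)
    n_dyads = 10
    trials = []
    for d in range(n_dyads):
        fast = SubjectProfile(
            f"d{d:02d}_fast",
            AD_LAW_FAST[0] * rng.lognormal(0, 0.08),
            AD_LAW_FAST[1] * rng.lognormal(0, 0.05), duration_cv=0.05)
        slow = SubjectProfile(
            f"d{d:02d}_slow",
            AD_LAW_SLOW[0] * rng.lognormal(0, 0.08),
            AD_LAW_SLOW[1] * rng.lognormal(0, 0.05), duration_cv=0.05)
        for nu in VISCOUS_LOADS:
            cfg = SessionConfig(trials_per_target_per_direction=2,
                                viscosity=nu, seed=SEED + 100 * d)
            for prof in (fast, slow):
                trials += generate_solo_session(
                    prof, cfg, rng=np.random.default_rng(rng.integers(2**31)))
        for kappa in (0.5, 1.6):
            cfg = SessionConfig(trials_per_target_per_direction=2,
                                stiffness=kappa, seed=SEED + 100 * d + 50)
            trials += generate_dyad_session(
                fast, slow, cfg, coordination="common_plan",
                rng=np.random.default_rng(rng.integers(2**31)))
    manifest = write_session(trials, OUT, manifest_extra={"seed": SEED})
    n_dyadic = sum(t.q_partner is not None for t in trials)
    print(f"wrote {len(trials)} trials ({n_dyadic} dyadic) -> {manifest.parent}")


if __name__ == "__main__":
    main()
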