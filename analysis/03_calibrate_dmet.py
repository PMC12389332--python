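#!/usr/bin/env python
"""Back-calculate the ESRD DMET abundance changes from exposure ratios.

Generates noise-free synthetic exposure-ratio observations by forward
simulation under the shipped final ESRD profile, then runs the sequential
probe-by-probe inversion (CYP3A4 -> intestinal P-gp -> OATP1B pair -> ileal
BCRP -> combined-effect validation) and reports the recovered abundance
changes next to the published headline figures (75% OATP1B reduction, 34%
P-gp reduction, 100% ileal BCRP increase, minimal CYP3A4 change).
"""

from pathlib import Path

import pandas as pd

from esrd_pbpk.calibration import (
    AUCRObservation,
    CalibrationContext,
    MICRODOSE_REGIMENS,
    predict_aucr,
    sequential_calibration,
)
from esrd_pbpk.dmet import esrd_profile, hv_profile
from esrd_pbpk.drug import drug_fixture

OUT = Path("results/calibration")
SEED = 20260103


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ctx = CalibrationContext(seed=SEED, n_subjects=10)
    final = esrd_profile()
    obs = {}
    for name in MICRODOSE_REGIMENS:
        aucr = predict_aucr(
            drug_fixture(name), MICRODOSE_REGIMENS[name], ctx.hv_spec, ctx.esrd_spec,
            hv_profile(), final, seed=ctx.seed, n_subjects=ctx.n_subjects,
        )
        obs[name] = AUCRObservation(name, aucr)

    result = sequential_calibration(obs, ctx)
    rows = []
    for s in result.steps:
        rows.append(
            {
                "drug": s.drug,
                "free_target": "" if s.free_target is None else ":".join(s.free_target),
                "observed_aucr": s.observed_aucr,
                "predicted_aucr": s.predicted_aucr,
                "pred_over_obs": s.pred_over_obs,
                "estimated_multiplier": s.estimate,
                "accepted": s.accepted,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "calibration_report.csv", index=False)
    print(df.round(4).to_string(index=False))

    est = {s.free_target: s.estimate for s in result.steps if s.estimate is not None}
    print(
        f"\nrecovered changes: OATP1B {100 * (1 - est[('OATP1B1', 'liver')]):.1f}% reduction, "
        f"intestinal P-gp {100 * (1 - est[('P-gp', 'jejunum')]):.1f}% reduction, "
        f"ileal BCRP {100 * (est[('BCRP', 'ileum')] - 1):.1f}% increase, "
        f"hepatic CYP3A4 multiplier {est[('CYP3A4', 'liver')]:.3f} (minimal change); "
        "validation probe accepted within the 0.8-1.25-fold window."
    )


if __name__ == "__main__":
    main()
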