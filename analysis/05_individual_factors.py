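#!/usr/bin/env python
"""Individual clearance correction: screen covariates, select by LASSO,
refit, and show the before/after agreement.

Builds a synthetic 10-patient ESRD cohort with microbiome/lab covariates and
a planted two-genus effect on the dabigatran clearance ratio, simulates the
PBPK clearances, runs the correlation screen + LASSO(lambda_min) + OLS refit,
and reports the fitted correction equation and the improvement in agreement
between corrected PBPK and reference clearance.
"""

import warnings
from pathlib import Path

import pandas as pd

from esrd_pbpk.calibration import MICRODOSE_REGIMENS
from esrd_pbpk.drug import drug_fixture
from esrd_pbpk.individual import select_correction
from esrd_pbpk.nca import nca_table
from esrd_pbpk.population import chinese_esrd_spec, sample_cohort
from esrd_pbpk.synth import SyntheticStudySpec, gen_cohort_covariates, gen_observed_pk

OUT = Path("results/individual_factors")
SEED = 20260105


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = SyntheticStudySpec(seed=SEED)
    table, true_ratio = gen_cohort_covariates(study)
    cohort = sample_cohort(chinese_esrd_spec(), study.n_subjects, SEED)

    drug = drug_fixture("dabigatran")
    reg = MICRODOSE_REGIMENS["dabigatran"]
    pk = gen_observed_pk(drug, cohort, reg, residual_cv=0.0, seed=SEED)
    nca = nca_table(pk, reg.amount_mg)
    cl_pbpk = nca["cl_over_f"].to_numpy()
    cl_ppk = cl_pbpk / true_ratio  # reference clearance consistent with the planted model

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = select_correction(
            table.drop(columns="subject"), cl_pbpk, cl_ppk, drug="dabigatran", seed=SEED
        )

    rep.screen_stats.to_csv(OUT / "screen.csv", index=False)
    rep.per_subject.to_csv(OUT / "per_subject.csv", index=False)
    pd.DataFrame(
        [{"intercept": rep.equation.intercept, **rep.equation.coefficients,
          "lambda_min": rep.lambda_min}]
    ).to_csv(OUT / "equation.csv", index=False)

    print("correlation screen:")
    print(rep.screen_stats.round(4).to_string(index=False))
    terms = " + ".join(f"{c:.4g} x {n}" for n, c in rep.equation.coefficients.items())
    print(f"\nselected: {rep.selected}  (lambda_min = {rep.lambda_min:.4g})")
    print(f"correction ratio = {rep.equation.intercept:.4g} + {terms}")
    print(
        f"agreement with reference clearance: R^2 {rep.r2_before:.3f} before -> "
        f"{rep.r2_after:.3f} after correction (planted truth: "
        f"1.11 + 0.152 x Clostridium_XVIII + 0.0558 x Escherichia)"
    )
    spurious = set(rep.selected) - {"Clostridium_XVIII", "Escherichia"}
    if spurious:
        print(
            f"note: {sorted(spurious)} survive(s) the lambda_min fit in this replicate "
            "with a small coefficient - the known overselection of the CV-minimising "
            "penalty at n = 10; the planted effects dominate the equation."
        )


if __name__ == "__main__":
    main()
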