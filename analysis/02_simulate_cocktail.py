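#!/usr/bin/env python
"""Simulate the five-probe microdose cocktail in matched HV and ESRD cohorts.

Runs the single-dose cocktail (10 ug midazolam, 375 ug dabigatran etexilate,
10 ug pitavastatin, 50 ug rosuvastatin, 100 ug atorvastatin) in 10 matched
virtual subjects per population, writes tidy concentration tables and
per-subject NCA, and prints geometric-mean CL/F and the ESRD/HV exposure
ratio per probe.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from esrd_pbpk.calibration import MICRODOSE_REGIMENS
from esrd_pbpk.dmet import esrd_profile, hv_profile
from esrd_pbpk.drug import drug_fixture
from esrd_pbpk.nca import nca_table
from esrd_pbpk.pbpk import population_simulate
from esrd_pbpk.population import chinese_esrd_spec, chinese_hv_spec

OUT = Path("results/cocktail")
SEED = 20260102
N = 10


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    hv_spec, es_spec = chinese_hv_spec(), chinese_esrd_spec()
    prof = {"HV": hv_profile(), "ESRD": esrd_profile()}
    spec = {"HV": hv_spec, "ESRD": es_spec}

    nca_rows, conc_rows, summary = [], [], []
    for name in MICRODOSE_REGIMENS:
        drug = drug_fixture(name)
        reg = MICRODOSE_REGIMENS[name]
        auc = {}
        for label in ("HV", "ESRD"):
            s = population_simulate(
                drug, reg, spec[label], prof[label],
                n_trials=1, n_per_trial=N, seed=SEED, keep_results=True,
            )
            auc[label] = s.auc_geomean
            tidy_parts = []
            for j, res in enumerate(s.results):
                hourly = pd.DataFrame(
                    {
                        "drug": name, "population": label, "subject": j,
                        "time_h": res.t[::20], "conc": res.conc["plasma"][::20],
                    }
                )
                tidy_parts.append(hourly)
                if j < 3:  # archive a 2-hourly trace for the first subjects
                    conc_rows.append(hourly.iloc[::2])
            tidy = pd.concat(tidy_parts, ignore_index=True)
            nca = nca_table(tidy, reg.amount_mg)
            nca.insert(0, "population", label)
            nca.insert(0, "drug", name)
            nca_rows.append(nca)
        summary.append(
            {
                "drug": name,
                "auc_geomean_hv": auc["HV"],
                "auc_geomean_esrd": auc["ESRD"],
                "aucr_esrd_hv": auc["ESRD"] / auc["HV"],
            }
        )

    pd.concat(conc_rows, ignore_index=True).to_csv(OUT / "concentrations.csv", index=False, float_format="%.5g")
    pd.concat(nca_rows, ignore_index=True).to_csv(OUT / "nca.csv", index=False, float_format="%.6g")
    df = pd.DataFrame(summary)
    df.to_csv(OUT / "exposure_ratios.csv", index=False)
    print(f"{N} matched subjects per arm (seed {SEED}); exposure ratios under the final ESRD profile:")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        "\nmidazolam exposure falls (higher unbound fraction), every transporter "
        "substrate rises; these ratios are the inputs the calibration stage inverts."
    )


if __name__ == "__main__":
    main()
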