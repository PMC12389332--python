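#!/usr/bin/env python
"""Application scenarios: statin muscle exposure, DDI magnitudes, and the
Morris physiology screen.

Simulates (1) muscle exposure of the three statins under single- and
multiple-dose regimens in HV vs ESRD, (2) victim-perpetrator combinations in
both populations, and (3) a Morris elementary-effects screen of the
physiological inputs for the CYP3A4 probe's exposure.
"""

from pathlib import Path

import pandas as pd

from esrd_pbpk.calibration import MICRODOSE_REGIMENS
from esrd_pbpk.dmet import esrd_profile, hv_profile
from esrd_pbpk.drug import drug_fixture, inhibitor_fixture
from esrd_pbpk.population import chinese_esrd_spec, chinese_hv_spec, sample_individual
from esrd_pbpk.scenarios import ddi_scenario, morris_screening, muscle_exposure, physiology_model_function

OUT = Path("results/scenarios")
SEED = 20260104
DESIGN = dict(n_trials=2, n_per_trial=5, seed=SEED)

DDI_COMBOS = (
    ("midazolam", "itraconazole"),
    ("midazolam", "ritonavir"),
    ("pitavastatin", "rifampin"),
    ("rosuvastatin", "clarithromycin"),
    ("atorvastatin", "clarithromycin"),
    ("dabigatran", "verapamil"),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    hv_spec, es_spec = chinese_hv_spec(), chinese_esrd_spec()
    ph, pe = hv_profile(), esrd_profile()

    muscle_rows = []
    for statin in ("pitavastatin", "rosuvastatin", "atorvastatin"):
        for regimen in ("SD", "MD"):
            m = muscle_exposure(drug_fixture(statin), hv_spec, es_spec, ph, pe, regimen=regimen, **DESIGN)
            muscle_rows.append(
                {
                    "victim": m.victim, "regimen": m.regimen,
                    "muscle_auc_hv": m.muscle_auc_hv, "muscle_auc_esrd": m.muscle_auc_esrd,
                    "ratio_esrd_hv": m.ratio,
                }
            )
    muscle = pd.DataFrame(muscle_rows)
    muscle.to_csv(OUT / "muscle_exposure.csv", index=False)
    print("muscle exposure (geometric means, dose-interval AUC):")
    print(muscle.round(4).to_string(index=False))

    ddi_rows = []
    for victim, perp in DDI_COMBOS:
        for spec, prof in ((hv_spec, ph), (es_spec, pe)):
            s = ddi_scenario(
                drug_fixture(victim), inhibitor_fixture(perp), spec, prof, t_end=240.0, **DESIGN
            )
            ddi_rows.append(
                {
                    "victim": s.victim, "perpetrator": s.perpetrator, "population": s.population,
                    "aucr_w_wo": s.aucr_w_wo, "cmaxr_w_wo": s.cmaxr_w_wo,
                }
            )
    ddi = pd.DataFrame(ddi_rows)
    ddi.to_csv(OUT / "ddi.csv", index=False)
    print("\nDDI magnitudes (AUC ratio with/without perpetrator, 0-240 h):")
    print(ddi.round(3).to_string(index=False))

    # Morris screen on one ESRD reference subject (CYP3A4 probe exposure)
    ind = sample_individual(es_spec, SEED)
    f = physiology_model_function(
        drug_fixture("midazolam"), MICRODOSE_REGIMENS["midazolam"], ind, pe, t_end=48.0
    )
    ranges = {
        "hsa": (24.0, 46.0),
        "hematocrit": (0.24, 0.42),
        "agp": (0.6, 1.9),
        "kidney_volume": (80.0, 300.0),
        "kidney_density": (0.95, 1.15),
        "liver_density": (0.95, 1.15),
        "cardiac_output_scalar": (0.7, 1.3),
        "gastric_mrt": (0.4, 1.2),
        "colon_mrt": (18.0, 55.0),
    }
    res = morris_screening(f, ranges, r_trajectories=20, levels=4, seed=SEED)
    auc_ref = f({k: 0.5 * (lo + hi) for k, (lo, hi) in ranges.items()})
    morris = pd.DataFrame(
        {"parameter": list(res.mu_star), "mu_star": list(res.mu_star.values()),
         "sigma": [res.sigma[k] for k in res.mu_star]}
    )
    morris["mu_star_pct_of_auc"] = 100.0 * morris["mu_star"] / auc_ref
    morris = morris.sort_values("mu_star", ascending=False)
    morris.to_csv(OUT / "morris.csv", index=False)
    print("\nMorris screen of midazolam AUC (ESRD subject), mu* ranking:")
    print(morris.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(
        "\nserum albumin dominates (binding/unbound fraction); cardiac output and "
        "the density terms are inert in the reduced model and screen at mu* = 0; "
        "AGP is inert for an albumin-bound probe."
    )


if __name__ == "__main__":
    main()
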