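"""Structured-text (YAML) serialisation for population specs, DMET profiles,
drug models and inhibitor models, plus tidy-CSV writers for simulations.

Round-trips are exact: dumping a loaded object reproduces the file byte for
byte (sorted keys, default float representation).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .dmet import DMETEntry, DMETProfile
from .drug import ClintEntry, DrugModel, InhibitorExposure
from .population import (
    BloodChemistrySpec,
    CreatinineStratum,
    GITransitSpec,
    KidneySizeSpec,
    PopulationSpec,
)

__all__ = [
    "population_spec_to_dict", "population_spec_from_dict",
    "profile_to_dict", "profile_from_dict",
    "drug_to_dict", "drug_from_dict",
    "inhibitor_to_dict", "inhibitor_from_dict",
    "save_yaml", "load_population_spec", "load_profile", "load_drug",
    "load_inhibitor", "simulation_to_frames",
]

PathLike = Union[str, Path]


def population_spec_to_dict(spec: PopulationSpec) -> dict:
    return {
        "kind": "population_spec",
        "label": spec.label,
        "height_coeffs": {s: list(c) for s, c in spec.height_coeffs.items()},
        "weight_coeffs": {s: list(c) for s, c in spec.weight_coeffs.items()},
        "height_cv": spec.height_cv,
        "weight_cv": spec.weight_cv,
        "scr_strata": [
            {"sex": s.sex, "age_lo": s.age_lo, "age_hi": s.age_hi, "mean": s.mean, "cv": s.cv}
            for s in spec.scr_strata
        ],
        "blood": {
            sex: {
                "hematocrit_mean": b.hematocrit_mean, "hct_cv": b.hct_cv,
                "agp_mean": b.agp_mean, "agp_cv": b.agp_cv,
                "hsa_mean": b.hsa_mean, "hsa_cv": b.hsa_cv,
            }
            for sex, b in spec.blood.items()
        },
        "kidney": {
            "baseline": spec.kidney.baseline, "bw_coeff": spec.kidney.bw_coeff,
            "bh_coeff": spec.kidney.bh_coeff, "cv": spec.kidney.cv,
            "density": spec.kidney.density,
        },
        "gi": {
            "gastric_fasted": spec.gi.gastric_fasted, "gastric_fed": spec.gi.gastric_fed,
            "colon_residence": spec.gi.colon_residence,
            "colon_mrt_male": spec.gi.colon_mrt_male,
            "colon_mrt_female": spec.gi.colon_mrt_female,
        },
        "phenotype_freqs": {t: dict(f) for t, f in spec.phenotype_freqs.items()},
        "age_range": list(spec.age_range),
        "female_fraction": spec.female_fraction,
        "oat3_from_egfr": spec.oat3_from_egfr,
    }


def population_spec_from_dict(d: dict) -> PopulationSpec:
    return PopulationSpec(
        label=d["label"],
        height_coeffs={s: tuple(c) for s, c in d["height_coeffs"].items()},
        weight_coeffs={s: tuple(c) for s, c in d["weight_coeffs"].items()},
        height_cv=d["height_cv"],
        weight_cv=d["weight_cv"],
        scr_strata=[CreatinineStratum(**s) for s in d["scr_strata"]],
        blood={sex: BloodChemistrySpec(sex=sex, **b) for sex, b in d["blood"].items()},
        kidney=KidneySizeSpec(**d["kidney"]),
        gi=GITransitSpec(**d["gi"]),
        phenotype_freqs=d.get("phenotype_freqs", {}),
        age_range=tuple(d["age_range"]),
        female_fraction=d["female_fraction"],
        oat3_from_egfr=d["oat3_from_egfr"],
    )


def profile_to_dict(profile: DMETProfile) -> dict:
    return {
        "kind": "dmet_profile",
        "label": profile.label,
        "entries": [
            {
                "target": e.target,
                "tissue": e.tissue,
                "abundance": e.abundance,
                "activity_scores": dict(e.activity_scores),
            }
            for e in profile.entries.values()
        ],
        "overrides": {f"{t}:{tis}": m for (t, tis), m in profile.overrides.items()},
    }


def profile_from_dict(d: dict) -> DMETProfile:
    entries = {}
    for e in d["entries"]:
        entry = DMETEntry(e["target"], e["tissue"], e["abundance"], dict(e["activity_scores"]))
        entries[(entry.target, entry.tissue)] = entry
    overrides = {tuple(k.split(":", 1)): v for k, v in d.get("overrides", {}).items()}
    return DMETProfile(label=d["label"], entries=entries, overrides=overrides)


def drug_to_dict(drug: DrugModel) -> dict:
    return {
        "kind": "drug_model",
        "name": drug.name,
        "mw": drug.mw,
        "fu_hv": drug.fu_hv,
        "fu_esrd_ratio": drug.fu_esrd_ratio,
        "blood_plasma_ratio": drug.blood_plasma_ratio,
        "binding_protein": drug.binding_protein,
        "ka": drug.ka,
        "fa_passive": drug.fa_passive,
        "vss": drug.vss,
        "kp_muscle": drug.kp_muscle,
        "ps_liver": drug.ps_liver,
        "clint": {
            f"{t}:{tis}": {"value": c.value, "scale": c.scale}
            for (t, tis), c in drug.clint.items()
        },
        "cl_int_ic": drug.cl_int_ic,
        "cl_additional": drug.cl_additional,
        "prodrug_conversion_k": drug.prodrug_conversion_k,
    }


def drug_from_dict(d: dict) -> DrugModel:
    clint = {
        tuple(k.split(":", 1)): ClintEntry(v["value"], v["scale"])
        for k, v in d.get("clint", {}).items()
    }
    return DrugModel(
        name=d["name"], mw=d["mw"], fu_hv=d["fu_hv"], fu_esrd_ratio=d["fu_esrd_ratio"],
        blood_plasma_ratio=d["blood_plasma_ratio"], binding_protein=d["binding_protein"],
        ka=d["ka"], fa_passive=d["fa_passive"], vss=d["vss"], kp_muscle=d["kp_muscle"],
        ps_liver=d["ps_liver"], clint=clint, cl_int_ic=d["cl_int_ic"],
        cl_additional=d["cl_additional"], prodrug_conversion_k=d["prodrug_conversion_k"],
    )


def inhibitor_to_dict(inh: InhibitorExposure) -> dict:
    return {
        "kind": "inhibitor",
        "name": inh.name,
        "i_u": inh.i_u,
        "ki": dict(inh.ki),
        "mbi": {t: list(v) for t, v in inh.mbi.items()},
        "kdeg": inh.kdeg,
    }


def inhibitor_from_dict(d: dict) -> InhibitorExposure:
    return InhibitorExposure(
        name=d["name"], i_u=d["i_u"], ki=dict(d.get("ki", {})),
        mbi={t: tuple(v) for t, v in d.get("mbi", {}).items()}, kdeg=d["kdeg"],
    )


def save_yaml(obj_dict: dict, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj_dict, sort_keys=True))
    return path


def _load(path: PathLike, kind: str) -> dict:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("kind") != kind:
        raise ValueError(f"{path} is not a {kind} file (kind={d.get('kind')!r})")
    return d


def load_population_spec(path: PathLike) -> PopulationSpec:
    return population_spec_from_dict(_load(path, "population_spec"))


def load_profile(path: PathLike) -> DMETProfile:
    return profile_from_dict(_load(path, "dmet_profile"))


def load_drug(path: PathLike) -> DrugModel:
    return drug_from_dict(_load(path, "drug_model"))


def load_inhibitor(path: PathLike) -> InhibitorExposure:
    return inhibitor_from_dict(_load(path, "inhibitor"))


def simulation_to_frames(result, subject: int = 0):
    """Tidy (subject, time_h, compartment, conc_mg_per_L) plus a per-pathway
    cumulative elimination frame."""
    rows = []
    for comp, series in result.conc.items():
        rows.append(
            pd.DataFrame(
                {
                    "subject": subject,
                    "time_h": result.t,
                    "compartment": comp,
                    "conc_mg_per_L": series,
                }
            )
        )
    conc = pd.concat(rows, ignore_index=True)
    elim = pd.DataFrame(
        {"subject": subject, "pathway": list(result.eliminated),
         "amount_mg": [v[-1] for v in result.eliminated.values()]}
    )
    return conc, elim
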