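"""Synthetic study generation.

Everything the pipeline consumes can be generated here, emulating the
single-dose microdose-cocktail study design: a small ESRD cohort (default
n = 10), observed-like plasma concentration tables with proportional residual
error, and per-subject covariate tables (gut-microbiome genus relative
abundances plus liver labs) with planted linear effects on the clearance
ratio.  Genus abundances are generated marginally lognormal (the analysis
consumes per-genus columns, not full compositions); the default residual
error is 20% proportional, typical of microdose bioanalysis.

``make_fixtures`` writes the complete fixture set (five drugs, five
inhibitors, both population specs, both DMET profiles) as YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as _io
from .dmet import esrd_profile, hv_profile
from .drug import DRUG_FIXTURES, DoseRegimen, DrugModel, drug_fixture, inhibitor_fixture, INHIBITOR_FIXTURES
from .pbpk import simulate
from .population import chinese_esrd_spec, chinese_hv_spec

__all__ = [
    "SyntheticStudySpec",
    "gen_cohort_covariates",
    "gen_observed_pk",
    "make_fixtures",
    "DEFAULT_SAMPLING_TIMES",
]

#: clinical-style sampling schedule (h post-dose)
DEFAULT_SAMPLING_TIMES = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0, 72.0)

#: lognormal (mean, CV%) per genus relative abundance (percent scale) and lab
DEFAULT_MICROBIOME = {
    "Clostridium_XVIII": (1.5, 60.0),
    "Escherichia": (3.0, 60.0),
    "Bacteroides": (20.0, 60.0),
    "Megamonas": (0.15, 120.0),
}
DEFAULT_LABS = {
    "AST": (22.0, 35.0),  # U/L
    "TBIL": (8.0, 40.0),  # umol/L
    "ALT": (20.0, 45.0),  # U/L
}


@dataclass
class SyntheticStudySpec:
    n_subjects: int = 10
    drugs: Tuple[str, ...] = tuple(DRUG_FIXTURES)
    residual_error_cv: float = 20.0  # percent, proportional, on concentrations
    intercept: float = 1.11
    covariate_effects: Dict[str, float] = field(
        default_factory=lambda: {"Clostridium_XVIII": 0.152, "Escherichia": 0.0558}
    )
    ratio_noise_cv: float = 2.0  # percent, additive normal noise on the ratio
    microbiome: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MICROBIOME)
    )
    labs: Dict[str, Tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_LABS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.residual_error_cv < 0 or self.ratio_noise_cv < 0:
            raise ValueError("CVs must be non-negative")
        unknown = set(self.covariate_effects) - set(self.microbiome) - set(self.labs)
        if unknown:
            raise ValueError(f"planted effects on unknown covariates: {sorted(unknown)}")


def _lognormal_col(rng, n, mean, cv_pct):
    cv = cv_pct / 100.0
    sigma2 = np.log1p(cv * cv)
    return np.exp(np.log(mean) - 0.5 * sigma2 + np.sqrt(sigma2) * rng.standard_normal(n))


def gen_cohort_covariates(spec: SyntheticStudySpec, seed: Optional[int] = None):
    """Covariate table plus the true per-subject clearance ratio.

    ratio_i = intercept + sum(slope_j * covariate_ij) + N(0, sigma), with
    sigma = ratio_noise_cv% of the intercept.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    data = {}
    planted_genera = [g for g in spec.covariate_effects if g in spec.microbiome]
    latent = rng.standard_normal(n)  # shared community factor for co-occurring taxa
    for genus, (mean, cv) in spec.microbiome.items():
        cvf = cv / 100.0
        sigma2 = np.log1p(cvf * cvf)
        if genus in planted_genera:
            # effect-carrying genera co-occur (correlation ~0.9 on the log scale)
            z = 0.9 * latent + np.sqrt(1 - 0.9**2) * rng.standard_normal(n)
        else:
            z = rng.standard_normal(n)
        data[genus] = np.exp(np.log(mean) - 0.5 * sigma2 + np.sqrt(sigma2) * z)
    for lab, (mean, cv) in spec.labs.items():
        data[lab] = _lognormal_col(rng, n, mean, cv)
    table = pd.DataFrame(data)
    table.insert(0, "subject", np.arange(n))
    ratio = np.full(n, spec.intercept)
    for cov, slope in spec.covariate_effects.items():
        ratio = ratio + slope * table[cov].to_numpy()
    noise = rng.standard_normal(n) * (spec.ratio_noise_cv / 100.0) * spec.intercept
    return table, ratio + noise


def gen_observed_pk(
    drug: DrugModel,
    cohort: Sequence,
    regimen: DoseRegimen,
    residual_cv: float = 20.0,
    seed: int = 0,
    profile=None,
    times: Sequence[float] = DEFAULT_SAMPLING_TIMES,
) -> pd.DataFrame:
    """Observed-like tidy concentration table: simulate each subject, then
    apply mean-1 lognormal proportional residual error per sample."""
    if residual_cv < 0:
        raise ValueError("residual_cv must be non-negative")
    profile = profile if profile is not None else esrd_profile()
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    cv = residual_cv / 100.0
    sigma2 = np.log1p(cv * cv)
    rows = []
    for j, ind in enumerate(cohort):
        res = simulate(drug, regimen, ind, profile, t_end=float(times[-1]))
        conc = np.interp(times, res.t, res.conc["plasma"])
        if cv > 0:
            err = np.exp(-0.5 * sigma2 + np.sqrt(sigma2) * rng.standard_normal(times.size))
            conc = conc * err
        rows.append(pd.DataFrame({"subject": j, "time_h": times, "conc": conc}))
    return pd.concat(rows, ignore_index=True)


def make_fixtures(out_dir) -> List[Path]:
    """Write the complete YAML fixture set; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in DRUG_FIXTURES:
        written.append(_io.save_yaml(_io.drug_to_dict(drug_fixture(name)), out / f"drug_{name}.yaml"))
    for name in INHIBITOR_FIXTURES:
        written.append(
            _io.save_yaml(_io.inhibitor_to_dict(inhibitor_fixture(name)), out / f"inhibitor_{name}.yaml")
        )
    written.append(
        _io.save_yaml(_io.population_spec_to_dict(chinese_hv_spec()), out / "population_hv.yaml")
    )
    written.append(
        _io.save_yaml(_io.population_spec_to_dict(chinese_esrd_spec()), out / "population_esrd.yaml")
    )
    written.append(_io.save_yaml(_io.profile_to_dict(hv_profile()), out / "dmet_hv.yaml"))
    written.append(_io.save_yaml(_io.profile_to_dict(esrd_profile()), out / "dmet_esrd.yaml"))
    return written
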