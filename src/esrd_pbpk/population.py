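"""Virtual Chinese healthy-volunteer (HV) and end-stage renal disease (ESRD)
populations.

Each virtual individual carries the demographic, renal and blood-chemistry
covariates that drive drug disposition in the reduced PBPK model: body height
and weight from sex-specific CK-NET-style polynomials, serum creatinine from
sex x age strata, eGFR from the CKD-EPI 2009 creatinine equation (race
coefficient omitted for a Chinese population), haematocrit / albumin (HSA) /
alpha-1-acid glycoprotein (AGP), kidney volume, gastrointestinal residence
times, transporter/enzyme phenotypes, and the fractional renal OAT3 secretory
function derived from eGFR.

All "(mean, CV%)" parameters are sampled lognormally (positivity; matches the
convention of commercial PBPK population simulators).  Sampling draws a fixed
sequence of deviates per subject so that two populations sampled with the same
seed yield quantile-matched ("common random numbers") individuals — this is
what makes the abundance back-calculation noise-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CreatinineStratum",
    "BloodChemistrySpec",
    "KidneySizeSpec",
    "GITransitSpec",
    "VirtualIndividual",
    "PopulationSpec",
    "predict_body_size",
    "compute_egfr",
    "oat3_fraction",
    "sample_individual",
    "sample_cohort",
    "cohort_to_frame",
    "chinese_hv_spec",
    "chinese_esrd_spec",
]

DMET_TARGETS = ("CYP3A4", "OATP1B1", "OATP1B3", "P-gp", "BCRP", "OAT3")
PHENOTYPES = ("EM/T", "PM/T", "IM/T", "UM/T")

#: reference glomerular filtration rate, mL/min/1.73 m^2 (healthy adult)
EGFR_REFERENCE = 120.0


@dataclass(frozen=True)
class CreatinineStratum:
    """Serum creatinine (umol/L) for one sex over a half-open age band [lo, hi)."""

    sex: str
    age_lo: float
    age_hi: float
    mean: float
    cv: float  # percent

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.cv <= 0:
            raise ValueError("creatinine stratum requires mean > 0 and cv > 0")
        if not self.age_lo < self.age_hi:
            raise ValueError("age band must satisfy lo < hi")

    def covers(self, sex: str, age: float) -> bool:
        return sex == self.sex and self.age_lo <= age < self.age_hi


@dataclass(frozen=True)
class BloodChemistrySpec:
    sex: str
    hematocrit_mean: float  # percent
    hct_cv: float
    agp_mean: float  # g/L
    agp_cv: float
    hsa_mean: float  # g/L
    hsa_cv: float

    def __post_init__(self) -> None:
        if not (10.0 < self.hematocrit_mean < 60.0):
            raise ValueError("hematocrit mean out of physiological range")
        if min(self.agp_mean, self.hsa_mean) <= 0:
            raise ValueError("protein means must be positive")


@dataclass(frozen=True)
class KidneySizeSpec:
    baseline: float  # mL
    bw_coeff: float  # mL per kg
    bh_coeff: float  # mL per m
    cv: float  # percent
    density: float  # g/L

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("kidney density must be positive")


@dataclass(frozen=True)
class GITransitSpec:
    """Gastric / colonic residence times in hours."""

    gastric_fasted: float
    gastric_fed: float
    colon_residence: float
    colon_mrt_male: float
    colon_mrt_female: float

    def __post_init__(self) -> None:
        for v in (
            self.gastric_fasted,
            self.gastric_fed,
            self.colon_residence,
            self.colon_mrt_male,
            self.colon_mrt_female,
        ):
            if v <= 0:
                raise ValueError("GI residence times must be positive")

    def colon_mrt(self, sex: str) -> float:
        return self.colon_mrt_male if sex == "M" else self.colon_mrt_female


@dataclass
class VirtualIndividual:
    sex: str
    age: float
    bh: float  # cm
    bw: float  # kg
    scr: float  # umol/L
    egfr: float  # mL/min/1.73 m^2
    hematocrit: float  # fraction
    hsa: float  # g/L
    agp: float  # g/L
    kidney_volume: float  # mL
    gi_transit: GITransitSpec
    phenotypes: dict
    oat3_fraction: Optional[float]  # None -> take from DMET profile
    population: str = "HV"
    hsa_ref: float = 45.0  # population mean, used for fu individualisation
    agp_ref: float = 0.65

    def validate(self) -> None:
        if not 18.0 <= self.age <= 100.0:
            raise ValueError("age out of [18, 100]")
        if self.oat3_fraction is not None and not 0.0 <= self.oat3_fraction <= 1.0:
            raise ValueError("oat3_fraction out of [0, 1]")
        if not 0.05 < self.hematocrit < 0.65:
            raise ValueError("hematocrit out of range")


@dataclass
class PopulationSpec:
    label: str  # HV | ESRD
    height_coeffs: dict  # sex -> (c0, c1, c2), cm vs years
    weight_coeffs: dict  # sex -> (a0, a1), BW = exp(a0 + a1*BH)
    height_cv: float  # percent, inter-individual variability
    weight_cv: float
    scr_strata: list
    blood: dict  # sex -> BloodChemistrySpec
    kidney: KidneySizeSpec
    gi: GITransitSpec
    phenotype_freqs: dict = field(default_factory=dict)  # target -> {pheno: p}
    age_range: tuple = (20.0, 70.0)
    female_fraction: float = 0.5
    oat3_from_egfr: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction out of [0, 1]")
        for target, freqs in self.phenotype_freqs.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"phenotype frequencies for {target} do not sum to 1")

    def stratum_for(self, sex: str, age: float) -> CreatinineStratum:
        for s in self.scr_strata:
            if s.covers(sex, age):
                return s
        raise KeyError(f"no creatinine stratum covers sex={sex}, age={age}")

    @property
    def hsa_ref(self) -> float:
        return float(np.mean([b.hsa_mean for b in self.blood.values()]))

    @property
    def agp_ref(self) -> float:
        return float(np.mean([b.agp_mean for b in self.blood.values()]))


# ---------------------------------------------------------------------------
# deterministic covariate models


def predict_body_size(spec: PopulationSpec, sex: str, age: float):
    """Median body height (cm) and weight (kg) for a given sex and age.

    Height is a quadratic in age; weight is log-linear in height.  Population
    sampling adds lognormal inter-individual variability separately.
    """
    if not 18.0 <= age <= 100.0:
        raise ValueError("age out of [18, 100]")
    c0, c1, c2 = spec.height_coeffs[sex]
    bh = c0 + c1 * age + c2 * age**2
    a0, a1 = spec.weight_coeffs[sex]
    bw = math.exp(a0 + a1 * bh)
    return bh, bw


def compute_egfr(scr: float, age: float, sex: str) -> float:
    """CKD-EPI 2009 creatinine eGFR, mL/min/1.73 m^2.

    ``scr`` in umol/L (converted internally by /88.4).  The race coefficient
    is omitted (Chinese population).
    """
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    scr_mgdl = scr / 88.4
    if sex == "F":
        kappa, alpha, sexmul = 0.7, -0.329, 1.018
    elif sex == "M":
        kappa, alpha, sexmul = 0.9, -0.411, 1.0
    else:
        raise ValueError(f"unknown sex {sex!r}")
    r = scr_mgdl / kappa
    egfr = 141.0 * min(r, 1.0) ** alpha * max(r, 1.0) ** -1.209 * 0.993**age * sexmul
    return egfr


def oat3_fraction(egfr: float) -> float:
    """Fraction of healthy renal OAT-mediated secretory function at a given eGFR.

    OAT% = (1 - exp(-(eGFR / 43.9)^0.9)) x 100; returned on the 0-1 scale.
    Strictly increasing in eGFR, 0 at eGFR 0, asymptoting to 1.
    """
    if egfr < 0:
        raise ValueError("eGFR must be non-negative")
    return 1.0 - math.exp(-((egfr / 43.9) ** 0.9)) if egfr > 0 else 0.0


# ---------------------------------------------------------------------------
# sampling


def _lognormal(rng_z: float, mean: float, cv_pct: float) -> float:
    """Lognormal variate with the given arithmetic mean and CV%, from a
    standard-normal deviate (so populations stay quantile-matched)."""
    cv = cv_pct / 100.0
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return math.exp(mu + math.sqrt(sigma2) * rng_z)


def sample_individual(spec: PopulationSpec, rng) -> VirtualIndividual:
    """Sample one virtual subject.

    ``rng`` is a ``numpy.random.Generator`` or an integer seed.  The draw
    sequence (length and order) is identical for every spec, so the same seed
    produces quantile-matched HV and ESRD subjects.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    u_sex = rng.uniform()
    u_age = rng.uniform()
    z = rng.standard_normal(7)  # height, weight, scr, hct, agp, hsa, kidney
    u_pheno = rng.uniform(size=len(DMET_TARGETS))

    sex = "F" if u_sex < spec.female_fraction else "M"
    lo, hi = spec.age_range
    age = lo + u_age * (hi - lo)

    bh_med, _ = predict_body_size(spec, sex, age)
    bh = _lognormal(z[0], bh_med, spec.height_cv)
    a0, a1 = spec.weight_coeffs[sex]
    bw = _lognormal(z[1], math.exp(a0 + a1 * bh), spec.weight_cv)

    stratum = spec.stratum_for(sex, age)
    scr = _lognormal(z[2], stratum.mean, stratum.cv)
    egfr = compute_egfr(scr, age, sex)

    blood = spec.blood[sex]
    hct = _lognormal(z[3], blood.hematocrit_mean, blood.hct_cv) / 100.0
    agp = _lognormal(z[4], blood.agp_mean, blood.agp_cv)
    hsa = _lognormal(z[5], blood.hsa_mean, blood.hsa_cv)

    k = spec.kidney
    kidney_med = k.baseline + k.bw_coeff * bw + k.bh_coeff * (bh / 100.0)
    kidney_volume = _lognormal(z[6], kidney_med, k.cv)

    phenotypes = {}
    for target, u in zip(DMET_TARGETS, u_pheno):
        freqs = spec.phenotype_freqs.get(target, {"EM/T": 1.0})
        cum = 0.0
        chosen = "EM/T"
        for pheno in PHENOTYPES:
            cum += freqs.get(pheno, 0.0)
            if u < cum:
                chosen = pheno
                break
        phenotypes[target] = chosen

    ind = VirtualIndividual(
        sex=sex,
        age=age,
        bh=bh,
        bw=bw,
        scr=scr,
        egfr=egfr,
        hematocrit=hct,
        hsa=hsa,
        agp=agp,
        kidney_volume=kidney_volume,
        gi_transit=spec.gi,
        phenotypes=phenotypes,
        oat3_fraction=oat3_fraction(egfr) if spec.oat3_from_egfr else 1.0,
        population=spec.label,
        hsa_ref=spec.hsa_ref,
        agp_ref=spec.agp_ref,
    )
    ind.validate()
    return ind


def sample_cohort(spec: PopulationSpec, n: int, seed: int) -> list:
    """Sample ``n`` subjects from a single seeded stream."""
    rng = np.random.default_rng(seed)
    return [sample_individual(spec, rng) for _ in range(n)]


def cohort_to_frame(cohort) -> pd.DataFrame:
    rows = []
    for i, ind in enumerate(cohort):
        rows.append(
            {
                "subject": i,
                "population": ind.population,
                "sex": ind.sex,
                "age": ind.age,
                "bh": ind.bh,
                "bw": ind.bw,
                "scr": ind.scr,
                "egfr": ind.egfr,
                "hematocrit": ind.hematocrit,
                "hsa": ind.hsa,
                "agp": ind.agp,
                "kidney_volume": ind.kidney_volume,
                "oat3_fraction": ind.oat3_fraction,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# built-in population specifications
#
# The ESRD numbers are Chinese registry (CK-NET 2016) and hospital-cohort
# values for dialysis-dependent patients.  The HV comparator mirrors the
# commercial "Chinese healthy volunteers" population; values that are not in
# the public domain are physiologically plausible placeholders and are marked
# as such.  The ESRD gastric/colonic residence times are ~2x the HV values
# (renal-impairment prolongation), so the HV baseline is taken as half the
# ESRD figures.

_HEIGHT = {"M": (176.18, -0.2623, 0.0016), "F": (161.15, -0.1405, 0.0005)}
_WEIGHT = {"M": (1.9619, 0.01314), "F": (2.442, 0.01000)}


def chinese_esrd_spec() -> PopulationSpec:
    return PopulationSpec(
        label="ESRD",
        height_coeffs=dict(_HEIGHT),
        weight_coeffs=dict(_WEIGHT),
        height_cv=3.0,  # placeholder IIV (not published)
        weight_cv=15.0,  # placeholder IIV
        scr_strata=[
            CreatinineStratum("M", 18.0, 50.0, 800.0, 38.4),
            CreatinineStratum("M", 50.0, 120.0, 674.74, 42.45),
            # female bands normalised to disjoint intervals (most specific wins)
            CreatinineStratum("F", 18.0, 30.0, 800.0, 27.85),
            CreatinineStratum("F", 30.0, 60.0, 666.80, 33.44),
            CreatinineStratum("F", 60.0, 120.0, 533.32, 34.01),
        ],
        blood={
            "M": BloodChemistrySpec("M", 33.1, 17.18, 1.0388, 39.00, 35.12, 27.38),
            "F": BloodChemistrySpec("F", 32.7, 16.49, 1.0948, 34.08, 34.43, 26.75),
        },
        kidney=KidneySizeSpec(baseline=5.7, bw_coeff=1.04, bh_coeff=29.8, cv=23.4, density=1050.0),
        gi=GITransitSpec(
            gastric_fasted=0.80,
            gastric_fed=3.35,
            colon_residence=30.0,
            colon_mrt_male=36.72,
            colon_mrt_female=50.14,
        ),
        oat3_from_egfr=True,
    )


def chinese_hv_spec() -> PopulationSpec:
    return PopulationSpec(
        label="HV",
        height_coeffs=dict(_HEIGHT),
        weight_coeffs=dict(_WEIGHT),
        height_cv=3.0,
        weight_cv=15.0,
        # healthy creatinine (placeholder means/CVs, normal laboratory range)
        scr_strata=[
            CreatinineStratum("M", 18.0, 120.0, 72.0, 12.0),
            CreatinineStratum("F", 18.0, 120.0, 58.0, 12.0),
        ],
        blood={
            # placeholder healthy Chinese values
            "M": BloodChemistrySpec("M", 43.0, 7.0, 0.65, 20.0, 45.0, 6.0),
            "F": BloodChemistrySpec("F", 40.0, 7.0, 0.65, 20.0, 44.0, 6.0),
        },
        kidney=KidneySizeSpec(baseline=5.7, bw_coeff=1.04, bh_coeff=29.8, cv=23.4, density=1050.0),
        gi=GITransitSpec(
            gastric_fasted=0.40,
            gastric_fed=1.675,
            colon_residence=15.0,
            colon_mrt_male=18.36,
            colon_mrt_female=25.07,
        ),
        oat3_from_egfr=False,
    )
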