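"""Back-calculation of DMET abundance changes from ESRD/HV exposure ratios.

The estimation follows the sequential microdose-cocktail protocol: each probe
substrate isolates one pathway, whose abundance multiplier (relative to the
healthy-volunteer baseline) is solved so that the simulated AUC ratio between
matched virtual ESRD and HV cohorts equals the observed ratio.

Order matters and is fixed by the protocol:

1. midazolam        -> hepatic CYP3A4
2. dabigatran       -> jejunal P-gp (prodrug efflux)
3. pitavastatin     -> hepatic OATP1B1/OATP1B3 (locked pair)
4. rosuvastatin     -> ileal BCRP, with OATP1B fixed from step 3 and renal
                       OAT3 scaled per-subject by the eGFR equation
5. atorvastatin     -> validation only (no free multiplier)

Each step's estimate is frozen into the working ESRD profile before the next
step.  Cohorts are quantile-matched between populations (common random
numbers), so the inversion is deterministic for a given seed and the
root-finding (bisection on the log multiplier) recovers noise-free synthetic
observations essentially exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .dmet import DMETProfile, OATP1B_PAIR, hv_profile
from .drug import DoseRegimen, DrugModel, drug_fixture
from .pbpk import population_simulate
from .population import PopulationSpec, chinese_esrd_spec, chinese_hv_spec

__all__ = [
    "AUCRObservation",
    "CalibrationStep",
    "StepRecord",
    "CalibrationResult",
    "CalibrationContext",
    "BracketError",
    "within_window",
    "calibration_profile",
    "predict_aucr",
    "backcalc_abundance",
    "sequential_calibration",
    "DEFAULT_PROTOCOL",
    "MICRODOSE_REGIMENS",
]

Key = Tuple[str, str]

#: single-dose microdose cocktail (mg)
MICRODOSE_REGIMENS: Dict[str, DoseRegimen] = {
    "midazolam": DoseRegimen("oral", 0.010),
    "dabigatran": DoseRegimen("oral", 0.375),
    "pitavastatin": DoseRegimen("oral", 0.010),
    "rosuvastatin": DoseRegimen("oral", 0.050),
    "atorvastatin": DoseRegimen("oral", 0.100),
}

#: (drug, free (target, tissue)); None marks the validation-only step
DEFAULT_PROTOCOL: List[Tuple[str, Optional[Key]]] = [
    ("midazolam", ("CYP3A4", "liver")),
    ("dabigatran", ("P-gp", "jejunum")),
    ("pitavastatin", ("OATP1B1", "liver")),
    ("rosuvastatin", ("BCRP", "ileum")),
    ("atorvastatin", None),
]


class BracketError(RuntimeError):
    pass


@dataclass
class AUCRObservation:
    drug: str
    observed_aucr: float
    window_lo: float = 0.8
    window_hi: float = 1.25

    def __post_init__(self) -> None:
        if self.observed_aucr <= 0:
            raise ValueError("observed AUCR must be positive")
        if not self.window_lo < self.window_hi:
            raise ValueError("acceptance window must satisfy lo < hi")


@dataclass
class CalibrationStep:
    drug: str
    free_target: Optional[Key]
    fixed_assignments: Dict[Key, float] = field(default_factory=dict)
    bounds: Tuple[float, float] = (0.01, 10.0)

    def __post_init__(self) -> None:
        if self.free_target is not None and self.free_target in self.fixed_assignments:
            raise ValueError("free target cannot also be fixed")


@dataclass
class StepRecord:
    drug: str
    free_target: Optional[Key]
    estimate: Optional[float]
    predicted_aucr: float
    observed_aucr: float
    accepted: bool

    @property
    def pred_over_obs(self) -> float:
        return self.predicted_aucr / self.observed_aucr


@dataclass
class CalibrationResult:
    steps: List[StepRecord]
    profile_esrd: DMETProfile
    multipliers: Dict[Key, float]


@dataclass
class CalibrationContext:
    """Everything the inversion needs besides the free multiplier."""

    hv_spec: PopulationSpec = field(default_factory=chinese_hv_spec)
    esrd_spec: PopulationSpec = field(default_factory=chinese_esrd_spec)
    seed: int = 0
    n_subjects: int = 10  # matched subjects per arm (clinical cohort size)
    t_end: float = 72.0


def within_window(pred: float, obs: float, lo: float = 0.8, hi: float = 1.25) -> bool:
    """Inclusive predicted/observed acceptance check (default 0.8-1.25-fold;
    use (0.5, 2.0) for the looser model-validation criterion)."""
    if pred <= 0 or obs <= 0:
        raise ValueError("pred and obs must be positive")
    return lo <= pred / obs <= hi


def calibration_profile(fixed: Optional[Dict[Key, float]] = None) -> DMETProfile:
    """Working ESRD profile: HV abundances/activities (the back-calculation's
    starting assumption) with calibrated multipliers applied as overrides."""
    prof = hv_profile()
    prof.label = "ESRD"
    for (target, tissue), m in (fixed or {}).items():
        prof = prof.with_multiplier(target, tissue, m)
        prof.label = "ESRD"
    return prof


def predict_aucr(
    drug: DrugModel,
    regimen: DoseRegimen,
    hv_spec: PopulationSpec,
    esrd_spec: PopulationSpec,
    profile_hv: DMETProfile,
    profile_esrd: DMETProfile,
    seed: int = 0,
    n_subjects: int = 10,
    t_end: float = 72.0,
    _hv_auc_cache: Optional[dict] = None,
) -> float:
    """Geometric-mean AUC ratio ESRD/HV on quantile-matched virtual cohorts."""
    kwargs = dict(n_trials=1, n_per_trial=n_subjects, seed=seed, t_end=t_end)
    cache_key = (drug.name, seed, n_subjects, t_end)
    if _hv_auc_cache is not None and cache_key in _hv_auc_cache:
        hv_auc = _hv_auc_cache[cache_key]
    else:
        hv_auc = population_simulate(drug, regimen, hv_spec, profile_hv, **kwargs).auc_geomean
        if _hv_auc_cache is not None:
            _hv_auc_cache[cache_key] = hv_auc
    esrd_auc = population_simulate(drug, regimen, esrd_spec, profile_esrd, **kwargs).auc_geomean
    return esrd_auc / hv_auc


def backcalc_abundance(
    step: CalibrationStep,
    obs: AUCRObservation,
    context: CalibrationContext,
    rel_tol: float = 1e-3,
    bracket_tol: float = 1e-4,
) -> float:
    """Solve the free multiplier so predicted AUCR matches the observation.

    Bisection on the natural-log multiplier over ``step.bounds``; converged
    when |pred/obs - 1| <= ``rel_tol`` or the log-bracket is narrower than
    ``bracket_tol``.  Raises :class:`BracketError` when the observed AUCR is
    unattainable within the bounds.
    """
    drug = drug_fixture(step.drug)
    regimen = MICRODOSE_REGIMENS[step.drug]
    profile_hv = hv_profile()
    hv_cache: dict = {}

    def f(log_m: float) -> float:
        prof = calibration_profile(step.fixed_assignments)
        prof = prof.with_multiplier(*step.free_target, math.exp(log_m))
        prof.label = "ESRD"
        aucr = predict_aucr(
            drug,
            regimen,
            context.hv_spec,
            context.esrd_spec,
            profile_hv,
            prof,
            seed=context.seed,
            n_subjects=context.n_subjects,
            t_end=context.t_end,
            _hv_auc_cache=hv_cache,
        )
        return aucr / obs.observed_aucr - 1.0

    lo, hi = (math.log(b) for b in step.bounds)
    f_lo, f_hi = f(lo), f(hi)
    if abs(f_lo) <= rel_tol:
        return math.exp(lo)
    if abs(f_hi) <= rel_tol:
        return math.exp(hi)
    if f_lo * f_hi > 0:
        raise BracketError(
            f"{step.drug}: observed AUCR {obs.observed_aucr:.4g} not attainable over "
            f"multiplier bounds {step.bounds}; pred/obs-1 at bounds: {f_lo:.4g}, {f_hi:.4g}"
        )
    while hi - lo > bracket_tol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) <= rel_tol:
            return math.exp(mid)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return math.exp(0.5 * (lo + hi))


def sequential_calibration(
    observations: Dict[str, AUCRObservation],
    context: Optional[CalibrationContext] = None,
    protocol: Optional[List[Tuple[str, Optional[Key]]]] = None,
) -> CalibrationResult:
    """Run the probe-by-probe protocol, freezing each estimate into the
    working ESRD profile; the final step validates without freeing anything."""
    context = context or CalibrationContext()
    protocol = protocol if protocol is not None else DEFAULT_PROTOCOL
    fixed: Dict[Key, float] = {}
    records: List[StepRecord] = []
    profile_hv = hv_profile()
    for drug_name, free in protocol:
        obs = observations[drug_name]
        step = CalibrationStep(drug_name, free, fixed_assignments=dict(fixed))
        if free is not None:
            estimate = backcalc_abundance(step, obs, context)
            keys = list(OATP1B_PAIR) if free in OATP1B_PAIR else [free]
            for k in keys:
                fixed[k] = estimate
        else:
            estimate = None
        prof = calibration_profile(fixed)
        pred = predict_aucr(
            drug_fixture(drug_name),
            MICRODOSE_REGIMENS[drug_name],
            context.hv_spec,
            context.esrd_spec,
            profile_hv,
            prof,
            seed=context.seed,
            n_subjects=context.n_subjects,
            t_end=context.t_end,
        )
        records.append(
            StepRecord(
                drug=drug_name,
                free_target=free,
                estimate=estimate,
                predicted_aucr=pred,
                observed_aucr=obs.observed_aucr,
                accepted=within_window(pred, obs.observed_aucr, obs.window_lo, obs.window_hi),
            )
        )
    return CalibrationResult(steps=records, profile_esrd=calibration_profile(fixed), multipliers=fixed)
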