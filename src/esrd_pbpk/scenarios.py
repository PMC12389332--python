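"""Application scenarios: DDI magnitude, statin muscle exposure, and Morris
global sensitivity screening.

DDI scenarios compare exposure with and without a perpetrator on the *same*
virtual cohort (matched subjects), reporting geometric-mean AUC and Cmax
ratios.  When the perpetrator hits a pathway whose burden grows in ESRD
(compensatory routes reduced), the DDI magnitude exceeds the healthy-
volunteer value; inhibiting a pathway that ESRD itself reduces does not.

Muscle exposure is the muscle-compartment AUC over 0-72 h (single dose) or
over one dosing interval at steady state (multiple dose); in the
perfusion-limited model it is proportional to plasma exposure through
Kp_muscle.

Morris screening computes elementary effects on unit-scaled parameter ranges:
mu* (mean absolute elementary effect) ranks influence, sigma flags
non-linearity/interaction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .dmet import DMETProfile
from .drug import DoseRegimen, DrugModel, InhibitorExposure
from .pbpk import PopulationSummary, population_simulate, simulate
from .population import PopulationSpec, VirtualIndividual

__all__ = [
    "ScenarioResult",
    "MuscleExposureResult",
    "MorrisResult",
    "ddi_scenario",
    "muscle_exposure",
    "morris_screening",
    "physiology_model_function",
    "PHYSIOLOGY_PARAMETERS",
]


@dataclass
class ScenarioResult:
    victim: str
    perpetrator: Optional[str]
    population: str
    aucr_w_wo: float
    cmaxr_w_wo: float
    muscle_auc: float
    regimen: str  # SD | MD

    def __post_init__(self) -> None:
        if self.aucr_w_wo <= 0 or self.cmaxr_w_wo <= 0:
            raise ValueError("exposure ratios must be positive")


@dataclass
class MuscleExposureResult:
    victim: str
    regimen: str
    muscle_auc_hv: float
    muscle_auc_esrd: float

    @property
    def ratio(self) -> float:
        return self.muscle_auc_esrd / self.muscle_auc_hv


@dataclass
class MorrisResult:
    mu_star: Dict[str, float]
    sigma: Dict[str, float]
    trajectories: int

    @property
    def ranking(self) -> List[str]:
        return sorted(self.mu_star, key=self.mu_star.get, reverse=True)


def ddi_scenario(
    victim: DrugModel,
    perpetrator: InhibitorExposure,
    spec: PopulationSpec,
    profile: DMETProfile,
    n_trials: int = 10,
    n_per_trial: int = 10,
    seed: int = 0,
    regimen: Optional[DoseRegimen] = None,
    t_end: float = 72.0,
) -> ScenarioResult:
    """Geometric-mean AUC/Cmax ratio with vs without the perpetrator on a
    matched virtual cohort."""
    regimen = regimen or DoseRegimen("oral", 1.0)
    base = population_simulate(
        victim, regimen, spec, profile,
        n_trials=n_trials, n_per_trial=n_per_trial, seed=seed, t_end=t_end,
    )
    with_inh = population_simulate(
        victim, regimen, spec, profile,
        subjects=base.subjects, inhibitor=perpetrator, t_end=t_end,
    )
    return ScenarioResult(
        victim=victim.name,
        perpetrator=perpetrator.name,
        population=profile.label,
        aucr_w_wo=with_inh.auc_geomean / base.auc_geomean,
        cmaxr_w_wo=with_inh.cmax_geomean / base.cmax_geomean,
        muscle_auc=base.muscle_auc_geomean,
        regimen="MD" if regimen.n_doses > 1 else "SD",
    )


def _interval_muscle_auc(summary: PopulationSummary, t_lo: float, t_hi: float) -> np.ndarray:
    out = np.empty(len(summary.results))
    for j, res in enumerate(summary.results):
        mask = (res.t >= t_lo) & (res.t <= t_hi)
        out[j] = np.trapezoid(res.conc["muscle"][mask], res.t[mask])
    return out


def muscle_exposure(
    victim: DrugModel,
    spec_hv: PopulationSpec,
    spec_esrd: PopulationSpec,
    profile_hv: DMETProfile,
    profile_esrd: DMETProfile,
    regimen: str = "SD",
    dose_mg: float = 1.0,
    interval_h: float = 24.0,
    n_doses_md: int = 7,
    n_trials: int = 10,
    n_per_trial: int = 10,
    seed: int = 0,
) -> MuscleExposureResult:
    """Paired HV/ESRD muscle AUC (0-72 h single dose, or the last dosing
    interval of a multiple-dose regimen) on quantile-matched cohorts."""
    if victim.kp_muscle is None:
        raise ValueError("victim has no muscle partition coefficient")
    if regimen == "SD":
        reg = DoseRegimen("oral", dose_mg)
        t_lo, t_hi = 0.0, 72.0
        t_end = 72.0
    elif regimen == "MD":
        reg = DoseRegimen("oral", dose_mg, n_doses=n_doses_md, interval_h=interval_h)
        t_lo = (n_doses_md - 1) * interval_h
        t_hi = t_end = n_doses_md * interval_h
    else:
        raise ValueError("regimen must be 'SD' or 'MD'")
    kwargs = dict(n_trials=n_trials, n_per_trial=n_per_trial, seed=seed,
                  t_end=t_end, keep_results=True)
    hv = population_simulate(victim, reg, spec_hv, profile_hv, **kwargs)
    es = population_simulate(victim, reg, spec_esrd, profile_esrd, **kwargs)
    auc_hv = _interval_muscle_auc(hv, t_lo, t_hi)
    auc_es = _interval_muscle_auc(es, t_lo, t_hi)

    def gm(x):
        return float(np.exp(np.mean(np.log(x)))) if np.all(x > 0) else float("nan")

    return MuscleExposureResult(
        victim=victim.name,
        regimen=regimen,
        muscle_auc_hv=gm(auc_hv),
        muscle_auc_esrd=gm(auc_es),
    )


# ---------------------------------------------------------------------------
# Morris elementary-effects screening


def morris_screening(
    model: Callable[[Dict[str, float]], float],
    ranges: Dict[str, Tuple[float, float]],
    r_trajectories: int = 20,
    levels: int = 4,
    seed: int = 0,
) -> MorrisResult:
    """Morris one-at-a-time elementary-effects screen.

    ``model`` maps a {name: value} dict to a scalar output.  Elementary
    effects are computed on unit-scaled inputs (EE has units of output change
    per full parameter range), so for an additive linear model mu* equals the
    absolute coefficient times the range width.
    """
    if r_trajectories < 2:
        raise ValueError("need at least two trajectories")
    names = list(ranges)
    for n, (lo, hi) in ranges.items():
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ValueError(f"invalid range for {n}")
    k = len(names)
    p = levels
    delta = p / (2.0 * (p - 1.0))
    grid = np.arange(p - int(round(delta * (p - 1)))) / (p - 1.0)  # start levels
    rng = np.random.default_rng(seed)

    def scale(x_unit: np.ndarray) -> Dict[str, float]:
        return {
            n: ranges[n][0] + x_unit[i] * (ranges[n][1] - ranges[n][0])
            for i, n in enumerate(names)
        }

    ee: Dict[str, List[float]] = {n: [] for n in names}
    for traj in range(r_trajectories):
        x = rng.choice(grid, size=k)
        order = rng.permutation(k)
        try:
            f_x = model(scale(x))
        except Exception as exc:
            raise RuntimeError(f"model evaluation failed in trajectory {traj}") from exc
        for i in order:
            step = delta if x[i] + delta <= 1.0 + 1e-12 else -delta
            x_new = x.copy()
            x_new[i] = min(max(x[i] + step, 0.0), 1.0)
            try:
                f_new = model(scale(x_new))
            except Exception as exc:
                raise RuntimeError(f"model evaluation failed in trajectory {traj}") from exc
            ee[names[i]].append((f_new - f_x) / step)
            x, f_x = x_new, f_new
    mu_star = {n: float(np.mean(np.abs(ee[n]))) for n in names}
    sigma = {n: float(np.std(ee[n], ddof=1)) for n in names}
    return MorrisResult(mu_star=mu_star, sigma=sigma, trajectories=r_trajectories)


#: physiological factors screened for exposure sensitivity.  Cardiac output
#: and liver density are intentionally inert in the reduced model (flows and
#: liver volumes are fixed constants) and report mu* ~ 0.
PHYSIOLOGY_PARAMETERS = (
    "hsa",
    "hematocrit",
    "agp",
    "kidney_volume",
    "kidney_density",
    "liver_density",
    "cardiac_output_scalar",
    "gastric_mrt",
    "colon_mrt",
)


def physiology_model_function(
    drug: DrugModel,
    regimen: DoseRegimen,
    individual: VirtualIndividual,
    profile: DMETProfile,
    t_end: float = 72.0,
) -> Callable[[Dict[str, float]], float]:
    """Wrap the simulator as AUC_0-t(physiology dict) for Morris screening,
    perturbing a copy of the reference individual."""

    def f(params: Dict[str, float]) -> float:
        ind = copy.deepcopy(individual)
        for name, value in params.items():
            if name == "hsa":
                ind.hsa = value
            elif name == "hematocrit":
                ind.hematocrit = value
            elif name == "agp":
                ind.agp = value
            elif name == "kidney_volume":
                ind.kidney_volume = value
            elif name == "gastric_mrt":
                ind.gi_transit = replace(ind.gi_transit, gastric_fasted=value)
            elif name == "colon_mrt":
                ind.gi_transit = replace(
                    ind.gi_transit, colon_mrt_male=value, colon_mrt_female=value
                )
            elif name in ("kidney_density", "liver_density", "cardiac_output_scalar"):
                pass  # not wired in the reduced model
            else:
                raise KeyError(f"unknown physiology parameter {name!r}")
        res = simulate(drug, regimen, ind, profile, t_end=t_end)
        return float(np.trapezoid(res.conc["plasma"], res.t))

    return f
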