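"""Drug disposition models, dose regimens and perpetrator (inhibitor) models.

A :class:`DrugModel` collects the parameters the reduced PBPK simulator needs:
plasma binding (fu, binding protein, blood:plasma ratio), absorption (ka,
fraction available for absorption), distribution (Vss, muscle Kp), passive
hepatocellular permeability, and per-pathway intrinsic clearances keyed by
(target, tissue).  Intrinsic clearances are stored in the in-vitro convention
(uL/min per mg microsomal protein for enzymes, per 1e6 cells for transporters,
at the healthy-volunteer baseline abundance) together with an organ scaling
factor; the simulator converts ``value * scale`` to whole-organ L/h.

Five fixture models map onto the microdose-cocktail probe archetypes:

* ``midazolam``      - CYP3A4-only (hepatic + gut first-pass)
* ``dabigatran``     - P-gp prodrug, lumped first-order enterocyte conversion,
                       renally filtered active moiety
* ``pitavastatin``   - OATP1B-only hepatic uptake
* ``rosuvastatin``   - OATP1B uptake + ileal BCRP efflux + renal OAT3/BCRP
                       secretion (~28% renal fraction in HVs)
* ``atorvastatin``   - multi-pathway (CYP3A4, OATP1B, P-gp, BCRP)

Printed anchors are used where available (atorvastatin ileal BCRP CLint,T
6 uL/min; rosuvastatin renal OAT3/BCRP CLint,T 150 uL/min per 1e6 cells);
every other numeric value is a documented physiologically plausible
placeholder — pathway-ratio behaviour, not clinical exposure, is the model's
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

__all__ = [
    "ClintEntry",
    "DrugModel",
    "DoseRegimen",
    "InhibitorExposure",
    "drug_fixture",
    "inhibitor_fixture",
    "DRUG_FIXTURES",
    "INHIBITOR_FIXTURES",
]

Key = Tuple[str, str]

#: uL/min -> L/h
UL_MIN_TO_L_H = 60e-6


@dataclass(frozen=True)
class ClintEntry:
    """In-vitro intrinsic clearance at HV baseline abundance.

    ``value`` in uL/min per scaling unit; ``scale`` the number of scaling
    units in the whole organ (mg protein, 1e6 cells, ...).
    """

    value: float
    scale: float

    def __post_init__(self) -> None:
        if self.value < 0 or self.scale < 0:
            raise ValueError("clearances must be non-negative")

    @property
    def organ_l_h(self) -> float:
        return self.value * self.scale * UL_MIN_TO_L_H


@dataclass
class DrugModel:
    name: str
    mw: float  # g/mol
    fu_hv: float  # unbound fraction in plasma, HVs
    fu_esrd_ratio: float  # ESRD fu / HV fu
    blood_plasma_ratio: float  # at reference haematocrit 0.45
    binding_protein: Optional[str]  # "HSA" | "AGP" | None
    ka: float  # 1/h, lumen -> enterocyte
    fa_passive: float  # fraction of dose available for absorption
    vss: float  # L/kg
    kp_muscle: float  # muscle:plasma partition
    ps_liver: float  # L/h, passive sinusoidal permeability (whole liver)
    clint: Dict[Key, ClintEntry] = field(default_factory=dict)
    cl_int_ic: float = 0.0  # L/h, intracellular hepatic loss not in the profile
    cl_additional: float = 0.0  # L/h, first-order systemic (plasma) clearance
    prodrug_conversion_k: Optional[float] = None  # 1/h, enterocyte conversion
    colon_ka_fraction: float = 0.02  # colonic absorption relative to SI

    def __post_init__(self) -> None:
        if not 0.0 < self.fu_hv <= 1.0:
            raise ValueError("fu must be in (0, 1]")
        if self.fu_hv * self.fu_esrd_ratio > 1.0 + 1e-12:
            raise ValueError("ESRD fu exceeds 1")
        if not 0.0 <= self.fa_passive <= 1.0:
            raise ValueError("fa must be in [0, 1]")

    def fu(self, population: str = "HV") -> float:
        return self.fu_hv * (self.fu_esrd_ratio if population == "ESRD" else 1.0)


@dataclass
class DoseRegimen:
    route: str  # oral | iv
    amount_mg: float  # per dose
    n_doses: int = 1
    interval_h: float = 24.0

    def __post_init__(self) -> None:
        if self.amount_mg < 0:
            raise ValueError("dose must be non-negative")
        if self.route not in ("oral", "iv"):
            raise ValueError("route must be oral or iv")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def times(self):
        return [i * self.interval_h for i in range(self.n_doses)]

    @property
    def total_mg(self) -> float:
        return self.amount_mg * self.n_doses


@dataclass
class InhibitorExposure:
    """Perpetrator model with a static unbound exposure concentration.

    Competitive inhibition attenuates a pathway by 1/(1 + I_u/Ki); mechanism-
    based inactivation additionally applies the steady-state enzyme-amount
    ratio kdeg / (kdeg + kinact * I_u / (KI + I_u)).
    """

    name: str
    i_u: float  # static unbound concentration, uM
    ki: Dict[str, float] = field(default_factory=dict)  # target -> uM
    mbi: Dict[str, Tuple[float, float]] = field(default_factory=dict)  # target -> (KI uM, kinact 1/h)
    kdeg: float = 0.03  # 1/h, enzyme turnover for MBI

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.ki.values()):
            raise ValueError("Ki must be positive")
        if any(k <= 0 or kin < 0 for k, kin in self.mbi.values()):
            raise ValueError("MBI requires KI > 0 and kinact >= 0")

    def factor(self, target: str) -> float:
        f = 1.0
        if target in self.ki:
            f /= 1.0 + self.i_u / self.ki[target]
        if target in self.mbi:
            KI, kinact = self.mbi[target]
            rate = kinact * self.i_u / (KI + self.i_u)
            f *= self.kdeg / (self.kdeg + rate)
        return f

    def targets(self):
        return set(self.ki) | set(self.mbi)


# ---------------------------------------------------------------------------
# fixtures

# organ scaling placeholders (documented in the methods note):
_LIVER_MG = 72000.0  # mg microsomal protein (40 mg/g x 1800 g liver)
_LIVER_CELLS = 216000.0  # 1e6 hepatocytes (120e6 cells/g x 1800 g)
_GUT_MG = 150.0  # effective gut mg protein (tuned for ~50% gut extraction)
_GUT_CELLS = 8000.0  # 1e6 enterocytes, effective
_RENAL_CELLS = 950.0  # 1e6 proximal-tubule cells, effective


def _midazolam() -> DrugModel:
    return DrugModel(
        name="midazolam",
        mw=325.8,
        fu_hv=0.02,
        fu_esrd_ratio=1.5,
        blood_plasma_ratio=0.65,
        binding_protein="HSA",
        ka=3.0,
        fa_passive=0.95,
        vss=1.0,
        kp_muscle=1.5,
        ps_liver=500.0,
        clint={
            ("CYP3A4", "liver"): ClintEntry(240.0, _LIVER_MG),
            ("CYP3A4", "intestine"): ClintEntry(240.0, _GUT_MG),
        },
    )


def _dabigatran() -> DrugModel:
    # prodrug archetype: P-gp efflux acts on the ester in the enterocyte;
    # systemic parameters describe the active moiety (renally filtered).
    return DrugModel(
        name="dabigatran",
        mw=627.7,
        fu_hv=0.65,
        fu_esrd_ratio=1.0,  # binding low and unchanged in ESRD
        blood_plasma_ratio=0.9,
        binding_protein=None,
        ka=0.8,
        fa_passive=0.85,
        vss=0.9,
        kp_muscle=0.3,
        ps_liver=5.0,
        clint={
            ("P-gp", "jejunum"): ClintEntry(30.0, _GUT_CELLS),
        },
        cl_additional=0.5,
        prodrug_conversion_k=6.0,
        colon_ka_fraction=0.0,
    )


def _pitavastatin() -> DrugModel:
    return DrugModel(
        name="pitavastatin",
        mw=421.5,
        fu_hv=0.004,
        fu_esrd_ratio=1.25,
        blood_plasma_ratio=0.55,
        binding_protein="HSA",
        ka=2.0,
        fa_passive=0.9,
        vss=0.5,
        kp_muscle=1.0,
        ps_liver=20.0,
        clint={
            ("OATP1B1", "liver"): ClintEntry(300.0, _LIVER_CELLS),
            ("OATP1B3", "liver"): ClintEntry(200.0, _LIVER_CELLS),
        },
        cl_int_ic=30.0,
    )


def _rosuvastatin() -> DrugModel:
    return DrugModel(
        name="rosuvastatin",
        mw=481.5,
        fu_hv=0.12,
        fu_esrd_ratio=1.1,
        blood_plasma_ratio=0.69,
        binding_protein="HSA",
        ka=0.35,
        fa_passive=1.0,
        vss=1.9,
        kp_muscle=1.0,
        ps_liver=5.0,
        clint={
            ("OATP1B1", "liver"): ClintEntry(2.8, _LIVER_CELLS),
            ("OATP1B3", "liver"): ClintEntry(1.8, _LIVER_CELLS),
            ("BCRP", "ileum"): ClintEntry(60.0, _GUT_CELLS),
            ("BCRP", "liver"): ClintEntry(3.0, _LIVER_CELLS),
            # printed anchors: renal OAT3/BCRP CLint,T 150 uL/min per 1e6 cells
            ("OAT3", "renal"): ClintEntry(150.0, _RENAL_CELLS),
            ("BCRP", "renal"): ClintEntry(150.0, _RENAL_CELLS),
        },
        cl_int_ic=2.0,
        colon_ka_fraction=0.0,
    )


def _atorvastatin() -> DrugModel:
    return DrugModel(
        name="atorvastatin",
        mw=558.6,
        fu_hv=0.05,
        fu_esrd_ratio=1.15,
        blood_plasma_ratio=0.61,
        binding_protein="HSA",
        ka=2.0,
        fa_passive=0.95,
        vss=5.4,
        kp_muscle=1.5,
        ps_liver=50.0,
        clint={
            ("CYP3A4", "liver"): ClintEntry(30.0, _LIVER_MG),
            ("CYP3A4", "intestine"): ClintEntry(240.0, 100.0),
            ("OATP1B1", "liver"): ClintEntry(60.0, _LIVER_CELLS),
            ("OATP1B3", "liver"): ClintEntry(40.0, _LIVER_CELLS),
            ("P-gp", "jejunum"): ClintEntry(5.0, _GUT_CELLS),
            ("P-gp", "liver"): ClintEntry(1.0, _LIVER_CELLS),
            # printed anchor: BCRP-mediated efflux CLint,T 6 uL/min
            ("BCRP", "ileum"): ClintEntry(6.0, _GUT_CELLS),
            ("BCRP", "liver"): ClintEntry(1.0, _LIVER_CELLS),
        },
        cl_int_ic=2.0,
    )


DRUG_FIXTURES = {
    "midazolam": _midazolam,
    "dabigatran": _dabigatran,
    "pitavastatin": _pitavastatin,
    "rosuvastatin": _rosuvastatin,
    "atorvastatin": _atorvastatin,
}


def drug_fixture(name: str) -> DrugModel:
    try:
        return DRUG_FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown drug fixture {name!r}; have {sorted(DRUG_FIXTURES)}") from None


def _inhibitors() -> Dict[str, InhibitorExposure]:
    # static unbound exposures and interaction constants are placeholders
    # chosen for directionally realistic inhibition strengths.
    return {
        "rifampin": InhibitorExposure(
            "rifampin", i_u=1.0, ki={"OATP1B1": 0.5, "OATP1B3": 0.3}
        ),
        "itraconazole": InhibitorExposure(
            "itraconazole", i_u=0.01, ki={"CYP3A4": 0.0013, "P-gp": 0.008}
        ),
        "clarithromycin": InhibitorExposure(
            "clarithromycin",
            i_u=1.0,
            ki={"P-gp": 4.1, "OATP1B1": 5.0, "OATP1B3": 5.0},
            mbi={"CYP3A4": (5.49, 0.54)},
        ),
        "ritonavir": InhibitorExposure(
            "ritonavir", i_u=0.1, mbi={"CYP3A4": (0.17, 0.32)}
        ),
        "verapamil": InhibitorExposure(
            "verapamil", i_u=0.1, ki={"P-gp": 1.0}, mbi={"CYP3A4": (2.9, 0.06)}
        ),
    }


INHIBITOR_FIXTURES = tuple(_inhibitors())


def inhibitor_fixture(name: str) -> InhibitorExposure:
    inh = _inhibitors()
    try:
        return inh[name]
    except KeyError:
        raise KeyError(f"unknown inhibitor fixture {name!r}; have {sorted(inh)}") from None
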