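"""Drug-metabolising enzyme and transporter (DMET) abundance profiles.

A :class:`DMETProfile` holds, per (target, tissue), the abundance (absolute,
pmol/mg-protein or pmol/1e6 cells; relative for ileal BCRP) and the phenotype
activity scores (extensive / poor / intermediate / ultra-rapid metaboliser or
transporter).  The shipped ESRD profile differs from the HV profile only in
the calibrated entries:

* hepatic OATP1B1/OATP1B3 activity reduced to 25% (locked pair),
* jejunal P-gp activity reduced to 66%,
* ileal BCRP relative abundance doubled (0.78 -> 1.56),
* renal OAT3 activity reduced to 24.6% of HV (eGFR-derived).

The effective pathway multiplier used by the simulator is
``(abundance x activity)_population / (abundance x activity)_HV``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

__all__ = ["DMETEntry", "DMETProfile", "hv_profile", "esrd_profile", "OATP1B_PAIR"]

Key = Tuple[str, str]

#: hepatic OATP1B1 and OATP1B3 change synchronously with identical folds
OATP1B_PAIR = (("OATP1B1", "liver"), ("OATP1B3", "liver"))


@dataclass
class DMETEntry:
    target: str
    tissue: str
    abundance: float
    activity_scores: Dict[str, float]  # phenotype -> dimensionless

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")
        if any(v < 0 for v in self.activity_scores.values()):
            raise ValueError("activity scores must be non-negative")

    def activity(self, phenotype: str = "EM/T") -> float:
        return self.abundance * self.activity_scores[phenotype]


@dataclass
class DMETProfile:
    label: str  # HV | ESRD
    entries: Dict[Key, DMETEntry]
    #: free calibration overrides applied on top of the stored entries
    overrides: Dict[Key, float] = field(default_factory=dict)

    def entry(self, target: str, tissue: str) -> DMETEntry:
        try:
            return self.entries[(target, tissue)]
        except KeyError:
            raise KeyError(f"no DMET entry for ({target}, {tissue})") from None

    def multiplier(
        self,
        target: str,
        tissue: str,
        phenotype: str = "EM/T",
        reference: Optional["DMETProfile"] = None,
    ) -> float:
        """Pathway activity relative to the HV extensive-phenotype baseline."""
        ref = reference if reference is not None else hv_profile()
        base = ref.entry(target, tissue).activity("EM/T")
        if base == 0:
            return 0.0
        m = self.entry(target, tissue).activity(phenotype) / base
        return m * self.overrides.get((target, tissue), 1.0)

    def with_multiplier(self, target: str, tissue: str, value: float) -> "DMETProfile":
        """Copy of the profile with an extra multiplicative override.

        Hepatic OATP1B1/1B3 are locked: overriding either sets both.
        """
        new = copy.deepcopy(self)
        keys = [(target, tissue)]
        if (target, tissue) in OATP1B_PAIR:
            keys = list(OATP1B_PAIR)
        for k in keys:
            if k not in new.entries:
                raise KeyError(f"no DMET entry for {k}")
            new.overrides[k] = value
        return new


def _entry(target, tissue, abundance, em, pm=0.0, im=0.0, um=0.0) -> DMETEntry:
    return DMETEntry(
        target,
        tissue,
        abundance,
        {"EM/T": em, "PM/T": pm, "IM/T": im, "UM/T": um},
    )


def hv_profile() -> DMETProfile:
    """Chinese healthy-volunteer DMET abundances and activity scores."""
    entries = [
        _entry("CYP3A4", "liver", 120.0, 1.0),
        _entry("CYP3A4", "intestine", 57.3, 1.0),
        _entry("CYP3A4", "colon", 2.58, 1.0),
        _entry("OATP1B1", "liver", 3.1, 0.584, 0.21, 0.4, 0.81),
        _entry("OATP1B3", "liver", 3.08, 1.0),
        _entry("P-gp", "liver", 0.246, 1.0),
        _entry("P-gp", "jejunum", 0.4, 1.0),
        _entry("BCRP", "ileum", 0.78, 1.0, 0.37, 0.67, 0.0),
        _entry("BCRP", "liver", 0.103, 1.0, 0.37, 0.67, 0.0),
        _entry("BCRP", "renal", 0.120, 1.0, 0.37, 0.67, 0.0),
        _entry("OAT3", "renal", 1.320, 1.0),
    ]
    return DMETProfile("HV", {(e.target, e.tissue): e for e in entries})


def esrd_profile() -> DMETProfile:
    """Final calibrated Chinese ESRD DMET profile."""
    entries = [
        _entry("CYP3A4", "liver", 120.0, 1.0),
        _entry("CYP3A4", "intestine", 57.3, 1.0),
        _entry("CYP3A4", "colon", 2.58, 1.0),
        _entry("OATP1B1", "liver", 3.1, 0.146, 0.0525, 0.1, 0.2025),
        _entry("OATP1B3", "liver", 3.08, 0.25),
        _entry("P-gp", "liver", 0.246, 1.0),
        _entry("P-gp", "jejunum", 0.4, 0.66),
        _entry("BCRP", "ileum", 1.56, 1.0, 0.37, 0.67, 0.0),
        _entry("BCRP", "liver", 0.103, 1.0, 0.37, 0.67, 0.0),
        _entry("BCRP", "renal", 0.120, 1.0, 0.37, 0.67, 0.0),
        _entry("OAT3", "renal", 1.320, 0.246),
    ]
    return DMETProfile("ESRD", {(e.target, e.tissue): e for e in entries})
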