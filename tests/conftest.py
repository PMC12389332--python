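import numpy as np
import pytest

from esrd_pbpk.dmet import esrd_profile, hv_profile
from esrd_pbpk.drug import ClintEntry, DoseRegimen, DrugModel
from esrd_pbpk.population import (
    GITransitSpec,
    VirtualIndividual,
    chinese_esrd_spec,
    chinese_hv_spec,
)


@pytest.fixture(scope="session")
def hv_spec():
    return chinese_hv_spec()


@pytest.fixture(scope="session")
def esrd_spec():
    return chinese_esrd_spec()


@pytest.fixture(scope="session")
def hv_prof():
    return hv_profile()


@pytest.fixture(scope="session")
def esrd_prof():
    return esrd_profile()


def make_individual(egfr=100.0, hct=0.45, population="HV", **kwargs):
    """Handcrafted reference subject; hct 0.45 makes B:P equal the drug's
    stated value, so degenerate configurations have exact closed forms."""
    defaults = dict(
        sex="M",
        age=40.0,
        bh=170.0,
        bw=70.0,
        scr=72.0,
        egfr=egfr,
        hematocrit=hct,
        hsa=45.0,
        agp=0.65,
        kidney_volume=150.0,
        gi_transit=GITransitSpec(0.4, 1.675, 15.0, 18.36, 25.07),
        phenotypes={},
        oat3_fraction=1.0,
        population=population,
        hsa_ref=45.0,
        agp_ref=0.65,
    )
    defaults.update(kwargs)
    return VirtualIndividual(**defaults)


@pytest.fixture
def reference_individual():
    return make_individual()


def make_drug(**kwargs):
    """Minimal drug model; every pathway off unless supplied."""
    defaults = dict(
        name="testdrug",
        mw=300.0,
        fu_hv=1.0,
        fu_esrd_ratio=1.0,
        blood_plasma_ratio=1.0,
        binding_protein=None,
        ka=1.0,
        fa_passive=1.0,
        vss=0.5,
        kp_muscle=0.0,
        ps_liver=0.0,
        clint={},
    )
    defaults.update(kwargs)
    return DrugModel(**defaults)


@pytest.fixture
def iv_bolus():
    return DoseRegimen("iv", 10.0)
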