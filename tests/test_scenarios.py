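"""DDI and muscle-exposure scenarios; Morris sensitivity screening."""

import numpy as np
import pytest

from esrd_pbpk.calibration import MICRODOSE_REGIMENS
from esrd_pbpk.drug import ClintEntry, DoseRegimen, InhibitorExposure, drug_fixture, inhibitor_fixture
from esrd_pbpk.pbpk import simulate
from esrd_pbpk.scenarios import (
    PHYSIOLOGY_PARAMETERS,
    ddi_scenario,
    morris_screening,
    muscle_exposure,
    physiology_model_function,
)

from conftest import make_drug, make_individual

DESIGN = dict(n_trials=1, n_per_trial=4, seed=3)


class TestDDI:
    def test_no_shared_target_is_unity(self, hv_spec, hv_prof):
        perp = InhibitorExposure("none-shared", i_u=10.0, ki={"OAT3": 1.0})
        s = ddi_scenario(drug_fixture("midazolam"), perp, hv_spec, hv_prof, **DESIGN)
        assert s.aucr_w_wo == pytest.approx(1.0, abs=1e-9)
        assert s.cmaxr_w_wo == pytest.approx(1.0, abs=1e-9)

    def test_uptake_inhibition_raises_exposure(self, hv_spec, hv_prof):
        perp = InhibitorExposure("oatp-inh", i_u=1.0, ki={"OATP1B1": 1.0, "OATP1B3": 1.0})
        s = ddi_scenario(drug_fixture("pitavastatin"), perp, hv_spec, hv_prof, **DESIGN)
        assert s.aucr_w_wo > 1.0

    def test_esrd_ddi_magnitude_at_least_hv(self, hv_spec, esrd_spec, hv_prof, esrd_prof):
        # the CYP3A4 probe's inhibited pathway carries a larger burden in
        # ESRD (compensatory routes reduced), so the DDI magnitude grows;
        # a long window avoids truncating the prolonged ESRD terminal phase
        victim = drug_fixture("midazolam")
        perp = inhibitor_fixture("itraconazole")
        hv = ddi_scenario(victim, perp, hv_spec, hv_prof, t_end=240.0, **DESIGN)
        es = ddi_scenario(victim, perp, esrd_spec, esrd_prof, t_end=240.0, **DESIGN)
        assert es.aucr_w_wo >= hv.aucr_w_wo

    def test_closed_form_uptake_limited_bound(self, hv_prof):
        # liver-only, uptake-limited victim with fu*CLup << Q: AUCR_w/w-o
        # approaches the closed-form 1 + I_u/Ki
        drug = make_drug(
            fu_hv=0.01,
            clint={("OATP1B1", "liver"): ClintEntry(50.0, 1.0 / 60e-6)},  # 50 L/h organ
        )
        ind = make_individual(egfr=0.0)
        perp = InhibitorExposure("inh", i_u=1.0, ki={"OATP1B1": 1.0})
        reg = DoseRegimen("iv", 1.0)
        # long window: the slow terminal phase must be essentially complete
        base = simulate(drug, reg, ind, hv_prof, t_end=2000.0, grid_dt=0.25)
        inh = simulate(drug, reg, ind, hv_prof, inhibitor=perp, t_end=2000.0, grid_dt=0.25)
        aucr = np.trapezoid(inh.conc["plasma"], inh.t) / np.trapezoid(base.conc["plasma"], base.t)
        assert aucr == pytest.approx(2.0, rel=0.01)


class TestMuscleExposure:
    def test_zero_partition_zero_auc(self, hv_spec, esrd_spec, hv_prof, esrd_prof):
        victim = drug_fixture("pitavastatin")
        victim.kp_muscle = 0.0
        m = muscle_exposure(victim, hv_spec, esrd_spec, hv_prof, esrd_prof, regimen="SD", **DESIGN)
        assert np.isnan(m.ratio)  # geometric mean of zeros is undefined

    def test_muscle_auc_proportional_to_plasma(self, hv_prof):
        # perfusion-limited muscle: AUC_muscle = Kp x AUC_plasma once the
        # profile has fully decayed
        drug = make_drug(vss=0.5, kp_muscle=2.0, cl_additional=5.0)
        ind = make_individual(egfr=0.0)
        res = simulate(drug, DoseRegimen("iv", 10.0), ind, hv_prof, t_end=200.0)
        auc_p = np.trapezoid(res.conc["plasma"], res.t)
        auc_m = np.trapezoid(res.conc["muscle"], res.t)
        assert auc_m == pytest.approx(2.0 * auc_p, rel=5e-3)  # grid-resolution accuracy

    def test_statin_esrd_ratio_above_one(self, hv_spec, esrd_spec, hv_prof, esrd_prof):
        m = muscle_exposure(
            drug_fixture("rosuvastatin"), hv_spec, esrd_spec, hv_prof, esrd_prof, regimen="SD", **DESIGN
        )
        assert m.ratio > 1.0

    def test_multiple_dosing_amplifies_ratio(self, hv_spec, esrd_spec, hv_prof, esrd_prof):
        kwargs = dict(n_trials=1, n_per_trial=3, seed=3)
        sd = muscle_exposure(
            drug_fixture("rosuvastatin"), hv_spec, esrd_spec, hv_prof, esrd_prof, regimen="SD", **kwargs
        )
        md = muscle_exposure(
            drug_fixture("rosuvastatin"), hv_spec, esrd_spec, hv_prof, esrd_prof, regimen="MD", **kwargs
        )
        assert md.ratio >= sd.ratio


class TestMorris:
    def test_linear_model_mu_star_is_coefficient(self):
        res = morris_screening(
            lambda p: 2.0 * p["x1"] + 0.0 * p["x2"],
            {"x1": (0.0, 1.0), "x2": (0.0, 1.0)},
            r_trajectories=8,
            seed=0,
        )
        assert res.mu_star["x1"] == pytest.approx(2.0, abs=1e-12)
        assert res.mu_star["x2"] == pytest.approx(0.0, abs=1e-12)
        assert res.ranking[0] == "x1"

    def test_interaction_inflates_sigma(self):
        res = morris_screening(
            lambda p: p["x1"] * p["x2"], {"x1": (0.0, 1.0), "x2": (0.0, 1.0)},
            r_trajectories=12, seed=1,
        )
        assert res.sigma["x1"] > 0.0

    def test_seed_reproducibility(self):
        f = lambda p: p["a"] ** 2 + 3 * p["b"]
        kw = dict(ranges={"a": (0.0, 2.0), "b": (-1.0, 1.0)}, r_trajectories=6, seed=9)
        assert morris_screening(f, **kw).mu_star == morris_screening(f, **kw).mu_star

    def test_input_validation(self):
        with pytest.raises(ValueError):
            morris_screening(lambda p: 0.0, {"x": (1.0, 0.0)}, r_trajectories=4)
        with pytest.raises(ValueError):
            morris_screening(lambda p: 0.0, {"x": (0.0, 1.0)}, r_trajectories=1)

    def test_physiology_screen_inert_parameters(self, esrd_prof):
        # cardiac output and densities are deliberately inert in the reduced
        # model; binding protein and gastric residence are live
        ind = make_individual(egfr=10.0, population="ESRD", oat3_fraction=0.25)
        f = physiology_model_function(
            drug_fixture("midazolam"), MICRODOSE_REGIMENS["midazolam"], ind, esrd_prof, t_end=48.0
        )
        ranges = {
            "hsa": (25.0, 45.0),
            "hematocrit": (0.25, 0.40),
            "gastric_mrt": (0.4, 1.2),
            "cardiac_output_scalar": (0.7, 1.3),
            "liver_density": (0.9, 1.1),
        }
        res = morris_screening(f, ranges, r_trajectories=3, seed=2)
        assert res.mu_star["cardiac_output_scalar"] == pytest.approx(0.0, abs=1e-15)
        assert res.mu_star["liver_density"] == pytest.approx(0.0, abs=1e-15)
        assert res.mu_star["hsa"] > 0.0
        assert res.mu_star["gastric_mrt"] > 0.0
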