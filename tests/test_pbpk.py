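"""Reduced PBPK simulator: mass balance, closed forms, monotonicity."""

import numpy as np
import pytest
from scipy.linalg import expm

from esrd_pbpk.calibration import MICRODOSE_REGIMENS
from esrd_pbpk.drug import ClintEntry, DoseRegimen, drug_fixture
from esrd_pbpk.nca import nca_summary
from esrd_pbpk.pbpk import Q_MUSCLE_BLOOD, population_simulate, simulate

from conftest import make_drug, make_individual


def auc(res, comp="plasma"):
    return float(np.trapezoid(res.conc[comp], res.t))


class TestMassBalance:
    @pytest.mark.parametrize("name", sorted(MICRODOSE_REGIMENS))
    def test_fixture_drugs_hv(self, name, reference_individual, hv_prof):
        res = simulate(drug_fixture(name), MICRODOSE_REGIMENS[name], reference_individual, hv_prof)
        assert res.mass_balance_error() < 1e-6

    def test_esrd_subject_with_inhibitor(self, esrd_prof):
        from esrd_pbpk.drug import inhibitor_fixture

        ind = make_individual(egfr=8.0, population="ESRD", oat3_fraction=0.2)
        res = simulate(
            drug_fixture("rosuvastatin"),
            MICRODOSE_REGIMENS["rosuvastatin"],
            ind,
            esrd_prof,
            inhibitor=inhibitor_fixture("clarithromycin"),
        )
        assert res.mass_balance_error() < 1e-6

    def test_multiple_dose(self, reference_individual, hv_prof):
        reg = DoseRegimen("oral", 1.0, n_doses=3, interval_h=24.0)
        res = simulate(drug_fixture("atorvastatin"), reg, reference_individual, hv_prof, t_end=96.0)
        assert res.mass_balance_error() < 1e-6


class TestDegenerateClosedForms:
    def test_zero_dose_all_zero(self, reference_individual, hv_prof):
        res = simulate(make_drug(), DoseRegimen("iv", 0.0), reference_individual, hv_prof)
        assert np.all(res.conc["plasma"] == 0.0)
        assert all(np.all(v == 0.0) for v in res.eliminated.values())

    def test_one_compartment_iv(self, hv_prof):
        # CL 1 L/h, V 10 L, dose 10 mg: AUC = 10 mg.h/L, C(0) = 1, slope 0.1
        ind = make_individual(egfr=0.0)
        drug = make_drug(vss=10.0 / 70.0, cl_additional=1.0)
        res = simulate(drug, DoseRegimen("iv", 10.0), ind, hv_prof, t_end=72.0)
        summary = nca_summary(res.t, res.conc["plasma"], 10.0)
        assert res.conc["plasma"][0] == pytest.approx(1.0, rel=1e-3)
        assert summary.auc_0_inf == pytest.approx(10.0, rel=1e-3)
        assert summary.lambda_z == pytest.approx(0.1, rel=1e-3)

    def test_two_compartment_matrix_exponential_oracle(self, hv_prof):
        ind = make_individual(egfr=0.0)
        drug = make_drug(vss=40.0 / 70.0, kp_muscle=0.5, cl_additional=2.0)
        res = simulate(drug, DoseRegimen("iv", 10.0), ind, hv_prof, t_end=48.0)
        v_mus, kp, q = 0.4 * 70.0, 0.5, Q_MUSCLE_BLOOD * 1.0
        v_c = 40.0 - v_mus * kp
        A = np.array(
            [[-(2.0 + q) / v_c, q / (v_mus * kp)], [q / v_c, -q / (v_mus * kp)]]
        )
        for tc in (0.5, 2.0, 10.0, 40.0):
            oracle = (expm(A * tc) @ np.array([10.0, 0.0]))[0] / v_c
            sim = np.interp(tc, res.t, res.conc["plasma"])
            assert sim == pytest.approx(oracle, rel=1e-3)

    def test_all_clearances_zero_nothing_eliminated(self, hv_prof):
        ind = make_individual(egfr=0.0)
        res = simulate(make_drug(), DoseRegimen("iv", 5.0), ind, hv_prof, t_end=24.0)
        assert all(v[-1] == 0.0 for v in res.eliminated.values())


class TestLinearityAndMonotonicity:
    def test_dose_linearity(self, reference_individual, hv_prof):
        drug = drug_fixture("midazolam")
        lo = simulate(drug, DoseRegimen("oral", 0.01), reference_individual, hv_prof)
        hi = simulate(drug, DoseRegimen("oral", 0.02), reference_individual, hv_prof)
        assert auc(hi) == pytest.approx(2 * auc(lo), rel=1e-6)
        assert hi.conc["plasma"].max() == pytest.approx(2 * lo.conc["plasma"].max(), rel=1e-6)

    def test_auc_decreases_with_elimination_multiplier(self, reference_individual, hv_prof):
        # hepatic uptake pathway: stronger OATP1B -> lower exposure
        drug = drug_fixture("pitavastatin")
        aucs = []
        for m in (0.25, 1.0, 4.0):
            prof = hv_prof.with_multiplier("OATP1B1", "liver", m)
            aucs.append(auc(simulate(drug, MICRODOSE_REGIMENS["pitavastatin"], reference_individual, prof)))
        assert aucs[0] > aucs[1] > aucs[2]

    def test_bioavailability_decreases_with_gut_efflux(self, reference_individual, hv_prof):
        drug = drug_fixture("rosuvastatin")
        aucs = []
        for m in (0.5, 1.0, 2.0):
            prof = hv_prof.with_multiplier("BCRP", "ileum", m)
            aucs.append(auc(simulate(drug, MICRODOSE_REGIMENS["rosuvastatin"], reference_individual, prof)))
        assert aucs[0] > aucs[1] > aucs[2]

    def test_esrd_profile_raises_oatp_substrate_exposure(self, reference_individual, hv_prof, esrd_prof):
        # same subject, reduced hepatic uptake only -> higher plasma AUC
        drug = drug_fixture("pitavastatin")
        reg = MICRODOSE_REGIMENS["pitavastatin"]
        assert auc(simulate(drug, reg, reference_individual, esrd_prof)) > auc(
            simulate(drug, reg, reference_individual, hv_prof)
        )

    def test_prodrug_pgp_reduction_raises_exposure(self, reference_individual, hv_prof):
        drug = drug_fixture("dabigatran")
        reg = MICRODOSE_REGIMENS["dabigatran"]
        base = auc(simulate(drug, reg, reference_individual, hv_prof))
        reduced = auc(
            simulate(drug, reg, reference_individual, hv_prof.with_multiplier("P-gp", "jejunum", 0.66))
        )
        assert reduced > base


class TestPopulationSimulate:
    def test_bookkeeping_and_determinism(self, hv_spec, hv_prof):
        drug = drug_fixture("midazolam")
        reg = MICRODOSE_REGIMENS["midazolam"]
        a = population_simulate(drug, reg, hv_spec, hv_prof, n_trials=2, n_per_trial=3, seed=4)
        b = population_simulate(drug, reg, hv_spec, hv_prof, n_trials=2, n_per_trial=3, seed=4)
        assert len(a.subjects) == 6
        assert np.array_equal(a.auc, b.auc)
        assert a.auc_geomean == b.auc_geomean

    def test_variability_propagates(self, hv_spec, hv_prof):
        drug = drug_fixture("midazolam")
        s = population_simulate(
            drug, MICRODOSE_REGIMENS["midazolam"], hv_spec, hv_prof, n_trials=1, n_per_trial=6, seed=2
        )
        assert np.std(s.auc) > 0

    def test_invalid_design_rejected(self, hv_spec, hv_prof):
        with pytest.raises(ValueError):
            population_simulate(
                drug_fixture("midazolam"), MICRODOSE_REGIMENS["midazolam"], hv_spec, hv_prof,
                n_trials=0, n_per_trial=1, seed=0,
            )
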