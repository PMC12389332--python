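"""Covariate screening, LASSO selection and clearance correction."""

import warnings

import numpy as np
import pandas as pd
import pytest

from esrd_pbpk.individual import (
    CorrectionEquation,
    apply_correction,
    clf_ratio,
    correlation_screen,
    lasso_select,
    published_equation,
    select_correction,
)
from esrd_pbpk.synth import SyntheticStudySpec, gen_cohort_covariates

PLANTED = {"Clostridium_XVIII", "Escherichia"}


class TestRatio:
    @pytest.mark.parametrize("a,b,expected", [(2.0, 2.0, 1.0), (3.0, 2.0, 1.5)])
    def test_ratio(self, a, b, expected):
        assert clf_ratio(a, b) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            clf_ratio(2.0, 0.0)


class TestScreen:
    def test_identical_covariate_retained(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(1, 2, size=10)
        table = pd.DataFrame({"same": y, "noise": rng.standard_normal(10)})
        selected, stats = correlation_screen(table, y)
        assert "same" in selected
        row = stats.set_index("covariate").loc["same"]
        assert row["statistic"] == pytest.approx(1.0)

    def test_null_retention_rate_matches_alpha(self):
        # permuted ratios are retained at roughly the nominal 5% level
        rng = np.random.default_rng(42)
        y = rng.uniform(1, 2, size=10)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.permutation(y)
            table = pd.DataFrame({"x": x})
            selected, _ = correlation_screen(table, y)
            hits += "x" in selected
        assert 0.01 < hits / n_rep < 0.10

    def test_constant_covariate_excluded_with_warning(self):
        y = np.linspace(1, 2, 8)
        table = pd.DataFrame({"flat": np.ones(8), "x": y + 0.01 * np.arange(8)})
        with pytest.warns(UserWarning, match="zero variance"):
            selected, stats = correlation_screen(table, y)
        assert "flat" not in stats["covariate"].tolist()

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            correlation_screen(pd.DataFrame({"x": [1, 2, 3]}), [1, 2, 3])


class TestLasso:
    def test_planted_effect_recovery_single_seed(self):
        rng = np.random.default_rng(7)
        x1 = rng.uniform(0, 4, size=10)
        x2 = rng.standard_normal(10)
        y = 1.1 + 0.5 * x1 + rng.standard_normal(10) * 0.02 * 1.1
        X = pd.DataFrame({"x1": x1, "x2": x2})
        selected, eq, lam = lasso_select(X, y, seed=7)
        assert "x1" in selected
        assert eq.coefficients["x1"] == pytest.approx(0.5, rel=0.10)

    def test_constant_response_empty_selection(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        selected, eq, _ = lasso_select(X, np.full(10, 1.3))
        assert selected == []
        assert eq.intercept == pytest.approx(1.3)

    def test_duplicated_column_tie_break(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, size=10)
        y = 1.0 + 0.8 * x + rng.standard_normal(10) * 0.01
        X = pd.DataFrame({"a": x, "a_copy": x})
        with pytest.warns(UserWarning, match="duplicates"):
            selected, eq, _ = lasso_select(X, y, seed=3)
        assert selected == ["a"]


class TestApplyCorrection:
    def test_published_dabigatran_intercept(self):
        eq = published_equation("dabigatran")
        assert eq.predict({"Clostridium_XVIII": 0.0, "Escherichia": 0.0}) == pytest.approx(1.11)

    def test_published_dabigatran_at_unit_abundances(self):
        eq = published_equation("dabigatran")
        assert eq.predict({"Clostridium_XVIII": 1.0, "Escherichia": 1.0}) == pytest.approx(1.3178)

    def test_published_rosuvastatin_intercept(self):
        eq = published_equation("rosuvastatin")
        zeros = {"AST": 0.0, "TBIL": 0.0, "Bacteroides": 0.0, "Megamonas": 0.0}
        assert eq.predict(zeros) == pytest.approx(1.67)

    def test_correction_divides(self):
        eq = CorrectionEquation("d", 2.0)
        assert apply_correction(eq, {}, 10.0) == pytest.approx(5.0)

    def test_missing_covariate_named(self):
        eq = published_equation("rosuvastatin")
        with pytest.raises(KeyError, match="TBIL"):
            eq.predict({"AST": 1.0, "Bacteroides": 0.0, "Megamonas": 0.0})

    def test_nonpositive_ratio_flagged_uncorrected(self):
        eq = CorrectionEquation("d", -0.5)
        with pytest.warns(UserWarning, match="non-positive"):
            assert apply_correction(eq, {}, 10.0) == 10.0

    def test_exact_arithmetic_oracle(self):
        eq = published_equation("rosuvastatin")
        cov = {"AST": 30.0, "TBIL": 12.0, "Bacteroides": 18.0, "Megamonas": 0.2}
        expected = 1.67 - 0.0581 * 30.0 + 0.0347 * 12.0 - 0.00596 * 18.0 + 1.847 * 0.2
        assert eq.predict(cov) == pytest.approx(expected, rel=1e-15)


class TestEndToEnd:
    def test_planted_covariates_retained_and_unbiased(self):
        """At the generator's default 2% ratio noise the screen+LASSO stage
        keeps the planted genera in >=90% of replicates and the OLS-refit
        slopes are unbiased well within 15%."""
        kept = 0
        slopes = []
        n_rep = 60
        for seed in range(n_rep):
            table, ratio = gen_cohort_covariates(SyntheticStudySpec(seed=seed))
            X = table.drop(columns="subject")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                screened, _ = correlation_screen(X, ratio)
                if not screened:
                    continue
                selected, eq, _ = lasso_select(X[screened], ratio, seed=seed)
            if PLANTED <= set(selected):
                kept += 1
                slopes.append(
                    [eq.coefficients["Clostridium_XVIII"], eq.coefficients["Escherichia"]]
                )
        assert kept / n_rep >= 0.90
        bias = np.mean(slopes, axis=0) / np.array([0.152, 0.0558]) - 1.0
        assert np.all(np.abs(bias) < 0.15)

    def test_correction_improves_agreement(self):
        """Applying the fitted equation strictly improves the coefficient of
        determination between corrected and reference clearance."""
        spec = SyntheticStudySpec(seed=4)
        table, ratio = gen_cohort_covariates(spec)
        rng = np.random.default_rng(4)
        cl_ppk = rng.uniform(1.0, 3.0, size=spec.n_subjects)
        cl_pbpk = cl_ppk * ratio
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = select_correction(
                table.drop(columns="subject"), cl_pbpk, cl_ppk, drug="dabigatran", seed=4
            )
        assert rep.r2_after > rep.r2_before
        assert set(rep.selected) <= set(rep.screened)
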