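"""Individual clearance correction: covariate screening, LASSO selection,
and correction equations.

The PBPK model integrates demographics, physiology and genotype; whatever
inter-individual variability remains shows up in the ratio between the
PBPK-predicted apparent clearance and a per-subject reference clearance
(here a population-PK-style reference).  Covariates not already inside the
PBPK model — gut-microbiome genus relative abundances and liver-function
labs — are screened by correlation against that ratio (p < alpha), the
survivors enter a cross-validated LASSO at the error-minimising penalty
(lambda_min), and the selected set is refit by ordinary least squares to give
an unshrunken correction equation in the covariates' original units:

    ratio = intercept + sum(coef_j * covariate_j)

Corrected CL/F = CL/F_PBPK / ratio, so a ratio > 1 (PBPK over-prediction)
corrects downwards.  The published reference equations for the dabigatran
and rosuvastatin probes are shipped for reuse:

    ratio_DAB = 1.11 + 0.152 * Clostridium_XVIII + 0.0558 * Escherichia
    ratio_RSV = 1.67 - 0.0581 * AST + 0.0347 * TBIL
                     - 0.00596 * Bacteroides + 1.847 * Megamonas
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrectionEquation",
    "SelectionReport",
    "clf_ratio",
    "correlation_screen",
    "lasso_select",
    "apply_correction",
    "select_correction",
    "published_equation",
]


@dataclass
class CorrectionEquation:
    drug: str
    intercept: float
    coefficients: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.intercept, *self.coefficients.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("equation coefficients must be finite")

    def predict(self, covariates) -> float:
        """Evaluate the correction ratio for one subject (mapping/Series)."""
        ratio = self.intercept
        for name, coef in self.coefficients.items():
            if name not in covariates:
                raise KeyError(f"missing covariate {name!r}")
            ratio += coef * float(covariates[name])
        return ratio


_PUBLISHED = {
    "dabigatran": CorrectionEquation(
        "dabigatran", 1.11, {"Clostridium_XVIII": 0.152, "Escherichia": 0.0558}
    ),
    "rosuvastatin": CorrectionEquation(
        "rosuvastatin",
        1.67,
        {"AST": -0.0581, "TBIL": 0.0347, "Bacteroides": -0.00596, "Megamonas": 1.847},
    ),
}


def published_equation(drug: str) -> CorrectionEquation:
    """Reference correction equation fitted on the clinical ESRD cohort."""
    try:
        eq = _PUBLISHED[drug]
    except KeyError:
        raise KeyError(f"no published correction equation for {drug!r}") from None
    return CorrectionEquation(eq.drug, eq.intercept, dict(eq.coefficients))


def clf_ratio(cl_pbpk: float, cl_ppk: float) -> float:
    """CL/F_PBPK over the per-subject reference CL/F."""
    if cl_pbpk <= 0 or cl_ppk <= 0:
        raise ValueError("clearances must be positive")
    return cl_pbpk / cl_ppk


def correlation_screen(
    table: pd.DataFrame,
    ratios: Sequence[float],
    alpha: float = 0.05,
    method: str = "spearman",
) -> Tuple[List[str], pd.DataFrame]:
    """Per-covariate correlation against the clearance ratio; keep p < alpha.

    Zero-variance covariates are excluded with a warning.  Spearman by
    default (robust at small n); Pearson selectable.
    """
    y = np.asarray(ratios, dtype=float)
    if len(table) != y.size or y.size < 4:
        raise ValueError("need >= 4 subjects and matching table/ratio lengths")
    corr = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    rows = []
    selected = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {col!r} has zero variance; excluded")
            continue
        r, p = corr(x, y)
        rows.append({"covariate": col, "statistic": float(r), "p_value": float(p)})
        if p < alpha:
            selected.append(col)
    return selected, pd.DataFrame(rows)


def _dedupe_columns(X: pd.DataFrame) -> pd.DataFrame:
    """Drop exactly duplicated covariate columns, keeping the first (the
    documented tie-break for collinear duplicates)."""
    seen = {}
    keep = []
    for col in X.columns:
        key = tuple(np.round(X[col].to_numpy(dtype=float), 12))
        if key in seen:
            warnings.warn(f"covariate {col!r} duplicates {seen[key]!r}; dropped")
            continue
        seen[key] = col
        keep.append(col)
    return X[keep]


def lasso_select(
    X: pd.DataFrame,
    y: Sequence[float],
    cv_folds: Optional[int] = None,
    seed: int = 0,
    drug: str = "",
) -> Tuple[List[str], CorrectionEquation, float]:
    """LASSO path at the cross-validated lambda_min, then OLS refit.

    Covariates are standardised internally for the penalised fit; the final
    equation is an unpenalised least-squares refit of the selected set in the
    original units.  Leave-one-out CV for n <= 12, else 10-fold.
    Returns (selected covariates, equation, lambda_min).
    """
    from sklearn.linear_model import LassoCV
    from sklearn.model_selection import LeaveOneOut

    y = np.asarray(y, dtype=float)
    n = y.size
    if n != len(X):
        raise ValueError("X and y lengths differ")
    X = _dedupe_columns(X.copy())
    cols = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) > 0]
    if not cols or np.ptp(y) == 0:
        return [], CorrectionEquation(drug, float(np.mean(y))), float("nan")
    Xv = X[cols].to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    Xs = (Xv - mu) / sd
    if cv_folds is None:
        cv = LeaveOneOut() if n <= 12 else 10
    else:
        if not 2 <= cv_folds <= n:
            raise ValueError("need n >= folds >= 2")
        cv = cv_folds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-n folds trigger convergence chatter
        lasso = LassoCV(cv=cv, random_state=seed, max_iter=50000).fit(Xs, y)
    lambda_min = float(lasso.alpha_)
    selected = [c for c, b in zip(cols, lasso.coef_) if abs(b) > 1e-10]
    if not selected:
        return [], CorrectionEquation(drug, float(np.mean(y))), lambda_min
    A = np.column_stack([np.ones(n), X[selected].to_numpy(dtype=float)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    eq = CorrectionEquation(drug, float(beta[0]), dict(zip(selected, map(float, beta[1:]))))
    return selected, eq, lambda_min


def apply_correction(eq: CorrectionEquation, covariates, cl_pbpk: float) -> float:
    """Corrected CL/F = CL/F_PBPK / predicted ratio.

    A non-positive predicted ratio is flagged (warning) and leaves the
    clearance uncorrected.
    """
    ratio = eq.predict(covariates)
    if ratio <= 0:
        warnings.warn(
            f"non-positive correction ratio {ratio:.4g} for {eq.drug or 'drug'}; "
            "correction not applied"
        )
        return cl_pbpk
    return cl_pbpk / ratio


@dataclass
class SelectionReport:
    drug: str
    screen_stats: pd.DataFrame
    screened: List[str]
    lambda_min: float
    selected: List[str]
    equation: CorrectionEquation
    r2_before: float
    r2_after: float
    per_subject: pd.DataFrame


def _r2(pred: np.ndarray, ref: np.ndarray) -> float:
    ss_res = float(np.sum((ref - pred) ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def select_correction(
    table: pd.DataFrame,
    cl_pbpk: Sequence[float],
    cl_ppk: Sequence[float],
    drug: str = "",
    alpha: float = 0.05,
    method: str = "spearman",
    seed: int = 0,
) -> SelectionReport:
    """Full stage: ratio -> correlation screen -> LASSO at lambda_min -> OLS
    refit -> before/after agreement between corrected and reference CL/F."""
    cl_pbpk = np.asarray(cl_pbpk, dtype=float)
    cl_ppk = np.asarray(cl_ppk, dtype=float)
    ratios = np.array([clf_ratio(a, b) for a, b in zip(cl_pbpk, cl_ppk)])
    screened, stats_df = correlation_screen(table, ratios, alpha=alpha, method=method)
    if screened:
        selected, eq, lam = lasso_select(table[screened], ratios, seed=seed, drug=drug)
    else:
        selected, eq, lam = [], CorrectionEquation(drug, float(np.mean(ratios))), float("nan")
    corrected = np.array(
        [apply_correction(eq, table.iloc[i], cl_pbpk[i]) for i in range(len(table))]
    )
    per_subject = pd.DataFrame(
        {
            "cl_pbpk": cl_pbpk,
            "cl_ppk": cl_ppk,
            "ratio": ratios,
            "cl_corrected": corrected,
        }
    )
    return SelectionReport(
        drug=drug,
        screen_stats=stats_df,
        screened=screened,
        lambda_min=lam,
        selected=selected,
        equation=eq,
        r2_before=_r2(cl_pbpk, cl_ppk),
        r2_after=_r2(corrected, cl_ppk),
        per_subject=per_subject,
    )
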