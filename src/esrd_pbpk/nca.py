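"""Non-compartmental analysis of concentration-time profiles.

AUC uses the linear-up / log-down trapezoidal rule: linear interpolation on
rising or flat segments (and whenever either endpoint is zero), logarithmic
on declining segments with both endpoints positive.  The terminal slope is a
log-linear regression over the post-Cmax suffix that maximises adjusted R^2
(minimum three points, Cmax excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["NCAResult", "auc_0_t", "terminal_slope", "nca_summary", "nca_table"]


@dataclass
class NCAResult:
    auc_0_t: float
    auc_0_inf: Optional[float]
    cmax: float
    tmax: float
    lambda_z: Optional[float]
    t_half: Optional[float]
    cl_over_f: Optional[float]
    n_lambda_points: int
    r2_adj: Optional[float]
    flags: Tuple[str, ...] = ()


def _check(t, c):
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    if t.ndim != 1 or t.size < 2 or t.size != c.size:
        raise ValueError("need matching 1-d arrays with at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return t, c


def auc_0_t(t, c) -> float:
    """Linear-up / log-down AUC over the observed span."""
    t, c = _check(t, c)
    auc = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c0 > 0 and c1 > 0:
            auc += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            auc += dt * 0.5 * (c0 + c1)
    return auc


def terminal_slope(t, c, min_points: int = 3):
    """Terminal log-linear slope (lambda_z, adjusted R^2, n points used).

    Candidate point sets are the suffixes of the positive concentrations
    after (and excluding) Cmax; the suffix with the highest adjusted R^2
    wins.  Returns ``(None, None, 0)`` when fewer than ``min_points``
    usable points exist or no negative slope is found.
    """
    t, c = _check(t, c)
    i_max = int(np.argmax(c))
    tt = t[i_max + 1 :]
    cc = c[i_max + 1 :]
    keep = cc > 0
    tt, cc = tt[keep], cc[keep]
    if tt.size < min_points:
        return None, None, 0
    logc = np.log(cc)
    best = None
    for start in range(tt.size - min_points + 1):
        x, y = tt[start:], logc[start:]
        n = x.size
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            r2 = 1.0 if ss_res < 1e-300 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        if best is None or r2_adj > best[1] + 1e-12:
            best = (-slope, r2_adj, n, intercept)
    if best is None:
        return None, None, 0
    return best[0], best[1], best[2]


def nca_summary(t, c, dose: float, min_points: int = 3) -> NCAResult:
    """Full NCA: AUCs, Cmax/Tmax, lambda_z, t1/2 and CL/F.

    CL/F = dose / AUC_0-inf; when no terminal phase can be estimated the
    result is flagged and CL/F falls back to dose / AUC_0-t.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    t, c = _check(t, c)
    auc_t = auc_0_t(t, c)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    lz, r2, n = terminal_slope(t, c, min_points=min_points)
    flags = []
    if lz is None:
        auc_inf = None
        t_half = None
        cl = dose / auc_t if auc_t > 0 else None
        flags.append("no_terminal_phase")
        if cl is not None:
            flags.append("cl_from_auc_0_t")
    else:
        auc_inf = auc_t + c[-1] / lz
        t_half = math.log(2.0) / lz
        cl = dose / auc_inf
    return NCAResult(
        auc_0_t=auc_t,
        auc_0_inf=auc_inf,
        cmax=cmax,
        tmax=tmax,
        lambda_z=lz,
        t_half=t_half,
        cl_over_f=cl,
        n_lambda_points=n,
        r2_adj=r2,
        flags=tuple(flags),
    )


def nca_table(df: pd.DataFrame, dose: float, subject_col: str = "subject",
              time_col: str = "time_h", conc_col: str = "conc") -> pd.DataFrame:
    """Per-subject NCA over a tidy (subject, time, concentration) table."""
    rows = []
    for subj, g in df.groupby(subject_col):
        g = g.sort_values(time_col)
        r = nca_summary(g[time_col].to_numpy(), g[conc_col].to_numpy(), dose)
        rows.append(
            {
                subject_col: subj,
                "auc_0_t": r.auc_0_t,
                "auc_0_inf": r.auc_0_inf,
                "cmax": r.cmax,
                "tmax": r.tmax,
                "lambda_z": r.lambda_z,
                "t_half": r.t_half,
                "cl_over_f": r.cl_over_f,
                "n_lambda_points": r.n_lambda_points,
                "r2_adj": r.r2_adj,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
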