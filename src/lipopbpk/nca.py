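"""Noncompartmental analysis of individual concentration-time profiles.

Conventions (stated explicitly because software defaults differ):

* lambda_z: log-linear OLS over candidate terminal windows of >= 3 points
  that exclude Tmax; the window maximising adjusted r^2 wins, with ties
  (within 1e-4) broken toward more points.
* AUC: linear-up / log-down trapezoid; AUC_inf adds C_last(observed)/lambda_z.
* MRT: AUMC_inf/AUC_inf with matching log-down segments and terminal
  extrapolation C_last*t_last/lambda + C_last/lambda^2.
* IV bolus: the concentration at t=0 is back-extrapolated log-linearly from
  the first two positive samples (carried flat if they do not decline), so
  the area of the unobserved initial interval is counted; Cmax/Tmax are
  reported from observed samples only.
* BLQ: pre-dose values are zero; embedded BLQ are dropped as missing;
  trailing BLQ are dropped.

With dose in ug/kg and concentrations in ug/ml, CL comes out in ml/kg/h and
Vss in ml/kg; with dose in mg the same formulas give L/h and L.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import linregress

LN2 = math.log(2.0)


class NotEstimableError(ValueError):
    """Terminal slope cannot be estimated from the profile."""


@dataclass
class ConcTimeProfile:
    """One subject/matrix concentration-time series.

    ``concentrations`` may contain NaN for BLQ/missing samples.
    """

    subject: str
    species: str
    dose: float                       # ug/kg (animals) or mg (absolute)
    matrix: str
    times: np.ndarray                 # h, strictly increasing
    concentrations: np.ndarray        # ug/ml, >= 0 or NaN

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.concentrations = np.asarray(self.concentrations, float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.concentrations < 0):
                raise ValueError("concentrations must be >= 0 or NaN")

    def cleaned(self) -> tuple[np.ndarray, np.ndarray]:
        """Apply the BLQ policy and return analyzable (t, c) arrays."""
        t, c = self.times.copy(), self.concentrations.copy()
        pre = (t <= 0) & np.isnan(c)
        c[pre] = 0.0
        keep = ~np.isnan(c)
        # drop trailing BLQ/missing then embedded missing
        t, c = t[keep], c[keep]
        pos = np.nonzero(c > 0)[0]
        if pos.size == 0:
            raise NotEstimableError(f"profile {self.subject}/{self.matrix} has no positive concentration")
        t, c = t[: pos[-1] + 1], c[: pos[-1] + 1]
        return t, c


@dataclass
class NCAResult:
    subject: str
    matrix: str
    dose: float
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float = np.nan
    lambda_z: float = np.nan
    lambda_z_points: int = 0
    adjusted_r2: float = np.nan
    t_half: float = np.nan
    mrt: float = np.nan
    cl: float = np.nan
    vss: float = np.nan

    def as_dict(self) -> dict:
        return {
            "subject": self.subject, "matrix": self.matrix, "dose": self.dose,
            "Cmax": self.cmax, "Tmax": self.tmax, "AUC_last": self.auc_last,
            "AUC_inf": self.auc_inf, "lambda_z": self.lambda_z,
            "lambda_z_points": self.lambda_z_points,
            "adjusted_r2": self.adjusted_r2, "t_half": self.t_half,
            "MRT": self.mrt, "CL": self.cl, "Vss": self.vss,
        }


def _adjusted_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def estimate_lambda_z(profile: ConcTimeProfile) -> tuple[float, int, float]:
    """Terminal slope by best-adjusted-r^2 window selection.

    Returns ``(lambda_z, n_points, adjusted_r2)``; raises
    :class:`NotEstimableError` when no declining window of >= 3 positive
    post-Tmax points exists.
    """
    t, c = profile.cleaned()
    pos = c > 0
    t, c = t[pos], c[pos]
    i_max = int(np.argmax(c))
    # candidates: suffixes of the post-Tmax points, Tmax excluded
    t_tail, c_tail = t[i_max + 1:], c[i_max + 1:]
    if t_tail.size < 3:
        raise NotEstimableError("fewer than 3 positive post-Tmax points")
    best = None
    for start in range(t_tail.size - 2):
        tt, cc = t_tail[start:], c_tail[start:]
        fit = linregress(tt, np.log(cc))
        if fit.slope >= 0:
            continue
        ar2 = _adjusted_r2(fit.rvalue ** 2, tt.size)
        if best is None or ar2 > best[2] + 1e-4:
            best = (-fit.slope, tt.size, ar2)
        # tie: keep the earlier (longer) window, already stored
    if best is None:
        raise NotEstimableError("no declining terminal window found")
    return best


def _auc_aumc_segments(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Linear-up/log-down AUC and AUMC over the observed span."""
    auc = aumc = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        dt = t2 - t1
        if c2 < c1 and c1 > 0 and c2 > 0:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
        else:
            auc += 0.5 * (c1 + c2) * dt
            aumc += 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def run_nca(profile: ConcTimeProfile, dose: float | None = None,
            iv_bolus: bool = True) -> NCAResult:
    """Full NCA of one profile.

    When the terminal slope is not estimable the extrapolated quantities
    (AUC_inf, CL, Vss, t_half, MRT) are NaN but AUC_last is still returned.
    """
    dose = profile.dose if dose is None else dose
    t, c = profile.cleaned()
    pos = c > 0
    tp, cp = t[pos], c[pos]
    i_max = int(np.argmax(cp))
    cmax, tmax = float(cp[i_max]), float(tp[i_max])

    # IV bolus: back-extrapolate C(0) if the profile does not start at 0
    if iv_bolus and t[0] > 0:
        if cp.size >= 2 and cp[1] < cp[0]:
            slope = (math.log(cp[1]) - math.log(cp[0])) / (tp[1] - tp[0])
            c0 = math.exp(math.log(cp[0]) - slope * tp[0])
        else:
            c0 = cp[0]
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[c0], c])

    auc_last, aumc_last = _auc_aumc_segments(t, c)
    res = NCAResult(subject=profile.subject, matrix=profile.matrix,
                    dose=dose, cmax=cmax, tmax=tmax, auc_last=auc_last)
    try:
        lam, npts, ar2 = estimate_lambda_z(profile)
    except NotEstimableError:
        return res
    c_last, t_last = c[-1], t[-1]
    res.lambda_z, res.lambda_z_points, res.adjusted_r2 = lam, npts, ar2
    res.t_half = LN2 / lam
    res.auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_last + c_last * t_last / lam + c_last / lam ** 2
    res.mrt = aumc_inf / res.auc_inf
    if dose is not None and dose > 0:
        res.cl = dose / res.auc_inf
        res.vss = res.cl * res.mrt
    return res


def summarize_by_dose(results: Sequence[NCAResult]):
    """Mean +/- SD per dose group for each NCA parameter (Table-style)."""
    import pandas as pd
    rows = [r.as_dict() for r in results]
    df = pd.DataFrame(rows)
    params = ["Cmax", "Tmax", "AUC_last", "AUC_inf", "lambda_z", "t_half",
              "MRT", "CL", "Vss"]
    g = df.groupby("dose")[params]
    out = g.agg(["mean", "std", "count"])
    out.columns = [f"{p}_{s}" for p, s in out.columns]
    return out.reset_index()
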