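"""Power-model dose-proportionality analysis.

The power model regresses ln(PK parameter) on ln(dose) by OLS; the slope
beta equals 1 under exact dose proportionality.  Rdnm = r^(beta-1) is the
dose-normalised geometric-mean ratio between the highest and lowest dose
(ratio r), and the classification compares the Rdnm confidence interval with
an acceptance interval (default 0.80-1.25): contained -> proportional,
disjoint -> nonproportional, otherwise inconclusive.

Group summaries (arithmetic mean +/- SD) are converted to geometric means
under a lognormal assumption, GM = mean / sqrt(1 + CV^2), before fitting;
individual-level values are fitted directly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm


DEFAULT_BOUNDS = (0.80, 1.25)


@dataclass(frozen=True)
class DoseGroupSummary:
    dose: float                       # mg/kg
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("summary mean must be > 0")
        if self.sd < 0 or self.n < 1 or self.dose <= 0:
            raise ValueError("invalid dose-group summary")


@dataclass
class PowerModelFit:
    """Results of one power-model fit (statsmodels-style results object)."""

    parameter: str
    slope: float
    slope_ci: tuple[float, float]      # (nan, nan) when df < 1
    intercept: float
    dose_ratio: float                  # r = dose_max / dose_min
    rdnm: float
    rdnm_ci: tuple[float, float]
    alpha: float
    n_obs: int
    df_resid: int
    classification: str | None = None
    bounds: tuple[float, float] | None = None
    predicted_gm: tuple[float, float] | None = None  # fitted value at (dmin, dmax)

    def summary(self) -> str:
        lo, hi = self.slope_ci
        rlo, rhi = self.rdnm_ci
        level = int(round(100 * (1 - self.alpha)))
        lines = [
            f"Power model: ln({self.parameter}) ~ ln(dose)   "
            f"[n={self.n_obs}, df={self.df_resid}]",
            f"  slope    {self.slope:8.4f}  ({level}% CI {lo:.4f}, {hi:.4f})",
            f"  Rdnm     {self.rdnm:8.4f}  ({level}% CI {rlo:.4f}, {rhi:.4f})"
            f"   [r = {self.dose_ratio:g}]",
        ]
        if self.predicted_gm is not None:
            lines.append(
                f"  predicted GM at extreme doses: "
                f"({self.predicted_gm[0]:.2f}, {self.predicted_gm[1]:.2f})")
        if self.classification is not None:
            lines.append(
                f"  conclusion: {self.classification} vs bounds {self.bounds}")
        return "\n".join(lines)


def gm_from_summary(mean: float, sd: float) -> float:
    """Geometric mean from arithmetic mean +/- SD under lognormality.

    GM = mean / sqrt(1 + (sd/mean)^2); always <= mean.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    return mean / math.sqrt(1.0 + (sd / mean) ** 2)


def fit_power_model(data, alpha: float = 0.10, parameter: str = "value",
                    bounds: tuple[float, float] | None = None) -> PowerModelFit:
    """Fit ln(value) ~ ln(dose) by OLS.

    ``data`` is either a sequence of :class:`DoseGroupSummary` (fitted as one
    geometric-mean point per dose) or an iterable of ``(dose, value)`` pairs
    / a DataFrame with ``dose`` and ``value`` columns (individual level).
    The slope CI uses the t distribution at the fit's residual df and is NaN
    when fewer than 3 points leave no residual degree of freedom.
    """
    if len(data) and isinstance(next(iter(data)), DoseGroupSummary):
        doses = np.array([g.dose for g in data], float)
        values = np.array([gm_from_summary(g.mean, g.sd) for g in data], float)
    else:
        try:
            doses = np.asarray(data["dose"], float)
            values = np.asarray(data["value"], float)
        except (TypeError, IndexError, KeyError):
            arr = np.asarray(list(data), float)
            doses, values = arr[:, 0], arr[:, 1]
    if np.unique(doses).size < 2:
        raise ValueError("power model needs >= 2 distinct doses")
    if np.any(values <= 0) or np.any(doses <= 0):
        raise ValueError("doses and values must be positive")

    x = sm.add_constant(np.log(doses))
    fit = sm.OLS(np.log(values), x).fit()
    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    df = int(fit.df_resid)
    if df >= 1:
        ci = fit.conf_int(alpha=alpha)
        slope_ci = (float(ci[1][0]), float(ci[1][1]))
    else:
        slope_ci = (math.nan, math.nan)
    r = float(doses.max() / doses.min())
    pred = (math.exp(intercept + slope * math.log(doses.min())),
            math.exp(intercept + slope * math.log(doses.max())))
    out = PowerModelFit(
        parameter=parameter, slope=slope, slope_ci=slope_ci,
        intercept=intercept, dose_ratio=r,
        rdnm=r ** (slope - 1.0),
        rdnm_ci=(r ** (slope_ci[0] - 1.0), r ** (slope_ci[1] - 1.0)),
        alpha=alpha, n_obs=int(fit.nobs), df_resid=df,
        predicted_gm=pred,
    )
    if bounds is not None:
        out.classification = classify(out, bounds)
        out.bounds = tuple(bounds)
    return out


def rdnm(fit: PowerModelFit) -> tuple[float, tuple[float, float]]:
    """Dose-normalised ratio r^(slope-1) with CI endpoints r^(CI-1)."""
    r = fit.dose_ratio
    return r ** (fit.slope - 1.0), (r ** (fit.slope_ci[0] - 1.0),
                                    r ** (fit.slope_ci[1] - 1.0))


def classify(fit: PowerModelFit,
             bounds: tuple[float, float] = DEFAULT_BOUNDS,
             rdnm_ci: tuple[float, float] | None = None) -> str:
    """Interval-inclusion decision rule on the Rdnm CI.

    ``rdnm_ci`` overrides the fit's own CI (e.g. an externally reported one).
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("degenerate bounds: low must be < high")
    cl, ch = rdnm_ci if rdnm_ci is not None else fit.rdnm_ci
    if math.isnan(cl) or math.isnan(ch):
        return "inconclusive"
    if lo <= cl and ch <= hi:
        return "proportional"
    if ch < lo or cl > hi:
        return "nonproportional"
    return "inconclusive"


def analyze_summaries(summaries: Sequence[DoseGroupSummary], alpha: float = 0.10,
                      parameter: str = "value",
                      bounds: tuple[float, float] = DEFAULT_BOUNDS) -> PowerModelFit:
    """Convenience: geometric-mean conversion + fit + classification."""
    return fit_power_model(list(summaries), alpha=alpha, parameter=parameter,
                           bounds=bounds)
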