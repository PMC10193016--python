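"""Concentration-response analysis: normalization to the negative control
and four-parameter logistic (4PL) fitting.

The model is Y = Min + (Max − Min) / (1 + (X / IC50)^Hill), with Y the
enzymatic activity as % of the untreated (negative) control, X the
compound concentration in μM, IC50 the half-maximal inhibitory
concentration and Hill the (positive) slope; activity falls from Max at
zero dose to Min at saturation. Maximal inhibition is 100 − Min (the
fitted lower asymptote), so a partial inhibitor plateaus below 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synth import four_pl

#: parameter bounds: Min %, Max %, IC50 μM, Hill
_BOUNDS_LO = np.array([-20.0, 50.0, 1e-3, 0.2])
_BOUNDS_HI = np.array([120.0, 150.0, 1e4, 5.0])

DEFAULT_R2_MIN = 0.18  # activity-call threshold on the goodness of fit


@dataclass
class FourPLParams:
    min_resp: float  # lower asymptote, % of control
    max_resp: float  # upper asymptote, % of control
    ic50: float      # μM
    hill: float

    def __post_init__(self):
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError("ic50 must be positive")


@dataclass
class DoseResponseFit:
    params: FourPLParams | None
    r_squared: float
    max_inhibition: float | None  # 100 − fitted Min, clipped to [0, 100]
    param_se: dict | None         # standard errors from the fit covariance
    reliable: bool
    clipped: bool = False
    activity_call: str | None = None

    @property
    def ic50(self):
        return self.params.ic50 if (self.params and self.reliable) else None


def normalize_activity(table: pd.DataFrame) -> pd.DataFrame:
    """Express raw rates as % of the mean negative control, per batch.

    ``table`` needs columns compound, concentration_um, replicate, rate,
    control_flag; an optional ``batch`` column scopes the controls (one
    batch assumed otherwise). Treated rows are returned with a
    ``pct_activity`` column; the negative-control mean maps to 100%.
    """
    required = {"compound", "concentration_um", "replicate", "rate",
                "control_flag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    table = table.copy()
    if "batch" not in table.columns:
        table["batch"] = "batch0"
    out = []
    for batch, group in table.groupby("batch", sort=False):
        neg = group.loc[group["control_flag"] == "negative", "rate"]
        if neg.empty:
            raise ValueError(f"batch {batch!r} has no negative control")
        scale = neg.mean()
        treated = group[group["control_flag"] == "treated"].copy()
        treated["pct_activity"] = 100.0 * treated["rate"] / scale
        out.append(treated)
    return pd.concat(out, ignore_index=True)


def _r_squared_on_means(norm_table: pd.DataFrame, params) -> float:
    means = norm_table.groupby("concentration_um")["pct_activity"].mean()
    y = means.to_numpy()
    yhat = four_pl(means.index.to_numpy(), *params)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def fit_4pl(norm_table: pd.DataFrame, on_means: bool = False) -> DoseResponseFit:
    """Least-squares 4PL fit of % activity against concentration.

    Multi-start (5 log-spaced IC50 starting points across the measured
    concentration range) to dodge local minima; R² is computed on the
    replicate means. The fit is flagged unreliable — and IC50 withheld —
    when the optimizer fails, the IC50 lands on a bound, or its standard
    error exceeds the estimate itself.
    """
    data = norm_table[norm_table["concentration_um"] > 0]
    x_all = data["concentration_um"].to_numpy(dtype=float)
    y_all = data["pct_activity"].to_numpy(dtype=float)
    if on_means:
        means = data.groupby("concentration_um")["pct_activity"].mean()
        x_all, y_all = means.index.to_numpy(), means.to_numpy()
    n_conc = len(np.unique(x_all))
    if n_conc < 4:
        raise ValueError(f"need >= 4 distinct concentrations, got {n_conc}")

    p0_min, p0_max = float(np.min(y_all)), float(np.max(y_all))
    p0_min = float(np.clip(p0_min, _BOUNDS_LO[0], _BOUNDS_HI[0]))
    p0_max = float(np.clip(p0_max, _BOUNDS_LO[1], _BOUNDS_HI[1]))
    starts = np.geomspace(x_all.min(), x_all.max(), 5)
    best, best_cov, best_sse = None, None, np.inf
    for ic50_0 in starts:
        try:
            popt, pcov = curve_fit(
                four_pl, x_all, y_all,
                p0=[p0_min, p0_max, float(ic50_0), 1.0],
                bounds=(_BOUNDS_LO, _BOUNDS_HI), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y_all - four_pl(x_all, *popt)) ** 2))
        if sse < best_sse:
            best, best_cov, best_sse = popt, pcov, sse

    if best is None:
        return DoseResponseFit(params=None, r_squared=0.0, max_inhibition=None,
                               param_se=None, reliable=False)

    se = np.sqrt(np.diag(best_cov))
    names = ("min_resp", "max_resp", "ic50", "hill")
    param_se = {n: (float(s) if np.isfinite(s) else None)
                for n, s in zip(names, se)}
    ic50 = float(best[2])
    at_bound = not (1.05 * _BOUNDS_LO[2] < ic50 < 0.95 * _BOUNDS_HI[2])
    se_bad = (param_se["ic50"] is None) or (param_se["ic50"] > ic50)
    reliable = not (at_bound or se_bad)
    r2 = _r_squared_on_means(norm_table[norm_table["concentration_um"] > 0],
                             best)
    max_inh = 100.0 - float(best[0])
    clipped = not 0.0 <= max_inh <= 100.0
    params = FourPLParams(min_resp=float(best[0]), max_resp=float(best[1]),
                          ic50=ic50, hill=float(best[3]))
    return DoseResponseFit(params=params, r_squared=r2,
                           max_inhibition=float(np.clip(max_inh, 0.0, 100.0)),
                           param_se=param_se, reliable=reliable,
                           clipped=clipped)


def classify_activity(fit: DoseResponseFit,
                      r2_min: float = DEFAULT_R2_MIN) -> str:
    """"inhibitor" iff the fit is reliable, R² >= r2_min (inclusive), and
    the maximal inhibition is significantly above zero (two standard
    errors of the lower asymptote); otherwise "inactive"."""
    if not fit.reliable or fit.r_squared < r2_min or fit.max_inhibition is None:
        fit.activity_call = "inactive"
        return fit.activity_call
    se_min = (fit.param_se or {}).get("min_resp")
    significant = (se_min is not None
                   and fit.max_inhibition - 2.0 * se_min > 0.0)
    fit.activity_call = "inhibitor" if significant else "inactive"
    return fit.activity_call
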