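"""Derived leaf gas-exchange metrics and stress-response summaries.

Works on long-format tables with one row per leaf measurement:
``plant_id, cultivar, treatment, daw, hour, gs, E, A, Ci, Tleaf``
(units: gs mol m-2 s-1, E mmol m-2 s-1, A umol m-2 s-1, Ci umol mol-1,
Tleaf degC).  Derived quantities:

* intrinsic water-use efficiency ``WUEi = A / gs``
  (umol CO2 mol-1 H2O), computed per record and then averaged;
* treatment percent changes between well-watered and waterlogged group
  means, with the *reduction* sign convention (positive = WL below WW);
* least-squares gs-response fits (A or E against gs, linear or
  quadratic);
* per-hour diurnal profiles (group means +/- SE within one DAW).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedResult

log = logging.getLogger(__name__)

PHYSIO_COLUMNS = ["plant_id", "cultivar", "treatment", "daw", "hour",
                  "gs", "E", "A", "Ci", "Tleaf"]


def compute_wuei(a: float, gs: float) -> float:
    """WUEi = A / gs; undefined (raises) for gs <= 0."""
    if gs <= 0:
        raise UndefinedResult(f"WUEi undefined for gs = {gs}")
    return a / gs


def add_wuei(records: pd.DataFrame) -> pd.DataFrame:
    """Append a ``WUEi`` column; rows with gs <= 0 keep the record but get
    a missing WUEi (logged), never a silent 0 or inf."""
    out = records.copy()
    gs = out["gs"].to_numpy(dtype=float)
    bad = ~(gs > 0)
    if bad.any():
        log.warning("WUEi undefined for %d record(s) with gs <= 0", int(bad.sum()))
    wuei = np.full(len(out), np.nan)
    wuei[~bad] = out["A"].to_numpy(dtype=float)[~bad] / gs[~bad]
    out["WUEi"] = wuei
    return out


def percent_change(ww_mean: float, wl_mean: float) -> float:
    """Percent *reduction* under waterlogging: 100 x (1 - WL/WW).

    Positive values are reductions, negative values increases."""
    if ww_mean == 0:
        raise UndefinedResult("percent change undefined for a zero WW mean")
    return 100.0 * (1.0 - wl_mean / ww_mean)


def percent_increase(ww_mean: float, wl_mean: float) -> float:
    """Percent *increase* under waterlogging: 100 x (WL/WW - 1)."""
    if ww_mean == 0:
        raise UndefinedResult("percent change undefined for a zero WW mean")
    return 100.0 * (wl_mean / ww_mean - 1.0)


def round_percent(x: float) -> int:
    """Round to the nearest whole percent, half away from zero."""
    return int(np.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class GroupSummary:
    cultivar: str
    treatment: str
    daw: int
    variable: str
    mean: float
    se: float  # NaN when n = 1
    n: int


def summarize_groups(
    records: pd.DataFrame,
    variables: list[str],
    by: tuple[str, ...] = ("cultivar", "treatment", "daw"),
) -> pd.DataFrame:
    """Mean, SE and n per group cell, long over ``variables``."""
    rows = []
    for keys, grp in records.groupby(list(by), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for variable in variables:
            vals = grp[variable].dropna().to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                continue
            rows.append(
                dict(zip(by, keys))
                | {
                    "variable": variable,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PolyFitResult:
    degree: int
    coefficients: np.ndarray  # highest power first (np.polyfit order)
    r_squared: float


def fit_gs_response(x, y, degree: int) -> PolyFitResult:
    """Least-squares polynomial fit of A (or E) against gs.

    ``degree`` must be chosen explicitly (1 = linear, 2 = quadratic);
    there is no silent model selection.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(x) == 0:
        raise ValueError("gs values are all identical: design is rank-deficient")
    coeffs = np.polyfit(x, y, degree)
    fitted = np.polyval(coeffs, x)
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PolyFitResult(degree=degree, coefficients=coeffs,
                         r_squared=float(np.clip(r2, 0.0, 1.0)))


def diurnal_profile(records: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-hour group means +/- SE for one day's measurements.

    All records must share a DAW (the diurnal course is a within-day
    summary).  Groups with no finite values are omitted with a log
    entry; n = 1 groups report the value with an undefined (NaN) SE.
    """
    daws = records["daw"].unique()
    if len(daws) != 1:
        raise ValueError(f"diurnal profile needs a single DAW, got {sorted(daws)}")
    rows = []
    for (cultivar, treatment, hour), grp in records.groupby(
        ["cultivar", "treatment", "hour"], sort=True
    ):
        vals = grp[variable].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            log.info("diurnal profile: empty group %s/%s/%s omitted",
                     cultivar, treatment, hour)
            continue
        rows.append({
            "cultivar": cultivar, "treatment": treatment, "hour": hour,
            "mean": float(vals.mean()),
            "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
            "n": len(vals),
        })
    return pd.DataFrame(rows)


def treatment_percent_changes(
    means: pd.DataFrame, variable: str, daw: int, increase: bool = False
) -> pd.DataFrame:
    """WL-vs-WW percent change per cultivar from a group-means table.

    ``means`` has columns cultivar, treatment, daw, variable, mean (the
    layout of :func:`summarize_groups` and of the bundled reference
    tables).  Returns raw and whole-percent-rounded values per cultivar.
    """
    sub = means[(means.variable == variable) & (means.daw == daw)]
    rows = []
    for cultivar, grp in sub.groupby("cultivar", sort=True):
        ww = grp.loc[grp.treatment == "WW", "mean"]
        wl = grp.loc[grp.treatment == "WL", "mean"]
        if len(ww) != 1 or len(wl) != 1:
            raise KeyError(f"need one WW and one WL mean for {cultivar}/DAW {daw}")
        fn = percent_increase if increase else percent_change
        raw = fn(float(ww.item()), float(wl.item()))
        rows.append({
            "cultivar": cultivar, "variable": variable, "daw": daw,
            "percent": raw, "percent_rounded": round_percent(raw),
        })
    return pd.DataFrame(rows)
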