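"""The slow second hydration stage and its temperature dependence.

After roughly 60 min of continuous hydration the impedance responses drift
linearly rather than exponentially.  The stage is characterised by the rate
of change ∆ (s⁻¹): the ordinary least-squares slope of the normalized
response against time over the 60–150 min window.  Per-temperature profiles
aggregate replicate ∆ values as mean ± SEM, and the initial-stage kinetics
can be re-run per temperature with a configurable conversion window (0–16
min by default, 0–6 min for responses that deviate at longer times).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import ResponseSeries
from .exceptions import DataError, FitError
from .kinetics import KineticsSummary, conversion_series, fit_first_order, summarize_kinetics

PROLONGED_WINDOW_S = (3600.0, 9000.0)  # 60-150 min


@dataclass
class RateFit:
    """Linear rate of change ∆ of a (normalized) response over a window."""

    delta_per_s: float
    intercept: float
    r_squared: float
    window_s: Tuple[float, float]
    n_points: int
    temperature_c: Optional[float] = None
    parameter_kind: str = ""
    replicate_id: str = ""


def fit_linear_rate(
    series: ResponseSeries,
    window_s: Tuple[float, float] = PROLONGED_WINDOW_S,
) -> RateFit:
    """OLS slope of value vs time inside the closed window (≥ 3 points).

    For a constant series the slope is 0 and R² is reported as 0.
    """
    lo, hi = window_s
    if not lo < hi:
        raise DataError(f"window must be ordered, got {window_s}")
    mask = (series.time_s >= lo) & (series.time_s <= hi)
    t = series.time_s[mask]
    v = series.values[mask]
    if len(t) < 3:
        raise FitError(
            f"linear rate fit needs ≥ 3 points in [{lo:g}, {hi:g}] s, have {len(t)}"
        )
    if np.ptp(v) == 0.0:
        return RateFit(
            delta_per_s=0.0,
            intercept=float(v[0]),
            r_squared=0.0,
            window_s=(lo, hi),
            n_points=len(t),
            temperature_c=series.temperature_c,
            parameter_kind=series.parameter_kind,
            replicate_id=series.replicate_id,
        )
    res = stats.linregress(t, v)
    return RateFit(
        delta_per_s=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        window_s=(lo, hi),
        n_points=len(t),
        temperature_c=series.temperature_c,
        parameter_kind=series.parameter_kind,
        replicate_id=series.replicate_id,
    )


def temperature_rate_profile(fits: Iterable[RateFit]) -> pd.DataFrame:
    """Group ∆ values by (temperature, parameter): mean ± SEM, ascending in T.

    SEM is reported as missing (NaN) for single-member groups rather than 0.
    """
    fits = list(fits)
    if len(fits) == 0:
        raise DataError("no rate fits supplied")
    for f in fits:
        if f.temperature_c is None:
            raise DataError("every rate fit needs a temperature label")
    frame = pd.DataFrame(
        {
            "temperature_c": [f.temperature_c for f in fits],
            "parameter": [f.parameter_kind for f in fits],
            "delta_per_s": [f.delta_per_s for f in fits],
        }
    )
    grouped = (
        frame.groupby(["temperature_c", "parameter"], as_index=False)
        .agg(
            mean_delta_per_s=("delta_per_s", "mean"),
            sem_delta=("delta_per_s", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
            n=("delta_per_s", "size"),
        )
        .sort_values(["parameter", "temperature_c"], kind="stable")
        .reset_index(drop=True)
    )
    return grouped


def initial_kinetics_by_temperature(
    series_by_temperature: Mapping[float, Sequence[ResponseSeries]],
    t_final_s: float = 960.0,
    t_final_overrides: Optional[Mapping[float, float]] = None,
    fit_window_s: Tuple[float, float] = (30.0, 120.0),
    r2_threshold: float = 0.75,
) -> KineticsSummary:
    """Initial-stage kinetics per temperature (Table-3-style procedure).

    The conversion window runs 0 to ``t_final_s`` (16 min by default); a
    per-temperature override (e.g. 6 min = 360 s for responses that deviate
    at longer times) can be supplied via ``t_final_overrides``.  Delegates
    to the kinetics module and groups by temperature.
    """
    overrides = dict(t_final_overrides or {})
    records = []
    for temperature, series_list in sorted(series_by_temperature.items()):
        if len(series_list) == 0:
            raise DataError(f"no series supplied for {temperature:g} °C")
        t_f = overrides.get(temperature, t_final_s)
        for s in series_list:
            conv = conversion_series(s, t_i_s=0.0, t_f_s=t_f)
            fit = fit_first_order(conv, window_s=fit_window_s)
            records.append(
                {
                    "label": f"{s.parameter_kind}@{temperature:g}C/{s.replicate_id}",
                    "group": f"{temperature:g}C",
                    "k_per_s": fit.k_per_s if fit.converging else np.nan,
                    "r_squared": fit.r_squared,
                }
            )
    return summarize_kinetics(records, r2_threshold=r2_threshold)
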