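"""First-order hydration kinetics of the initial stage.

The extent of hydration is tracked by the conversion factor

    α(t) = (EIR_i − EIR_t) / (EIR_i − EIR_f),

where EIR is the measured electrical impedance response, with i and f the
initial and final measurements of the protocol (0 and 16 min by default).
Under first-order decelerating kinetics, −ln(1 − α) = k t is linear in
time; the rate constant k (s⁻¹) is the slope of an ordinary least-squares
line fitted over the 30–120 s window, where the response is reliably linear
(earlier points carry the contact transient).  The hydration time to a
stated conversion follows as t_h = −ln(1 − α_target) / k, reported to whole
minutes (round half-up) as in the summary tables.

The smooth response curves behind the degree-of-hydration estimate are
power-law fits, Response = a·b^t + c with b ∈ (0, 1), excluding the first
30 s.  Two notions of the degree of hydration θ_h are computed from such a
fit: the literal 1 s finite difference of the fitted curve (a rate, s⁻¹)
and the cumulative fraction of the total fitted change completed by time t,
|f(t_start) − f(t)| / |f(t_start) − c| = 1 − b^(t − t_start); the cumulative
form is the reporting default (it is the quantity that sits near 95% at the
95%-conversion hydration time and is the only reading consistent with the
percentages reported alongside the rate constants).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ResponseSeries
from .exceptions import DataError, DegenerateSeriesError, FitError

ALPHA_OVERSHOOT_TOL = 1e-12


@dataclass
class ConversionSeries:
    """Pointwise conversion factor α over a measurement schedule."""

    time_s: np.ndarray
    alpha: np.ndarray
    t_initial_s: float
    t_final_s: float
    parameter_kind: str
    eir_initial: float
    eir_final: float


@dataclass
class FirstOrderFit:
    """Slope/intercept of −ln(1−α) vs t over the regression window."""

    k_per_s: float
    intercept: float
    r_squared: float
    window_s: Tuple[float, float]
    n_points: int
    converging: bool = True


@dataclass
class PowerLawFit:
    """Parameters of Response = a·b^t + c with b constrained to (0, 1)."""

    a: float
    b: float
    c: float
    t_start_s: float
    rmse: float
    degenerate: bool = False

    def __call__(self, t_s) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        return self.a * np.exp(np.log(self.b) * t) + self.c


@dataclass
class HydrationDegree:
    """Degree of hydration on a 1 s grid, in both interpretations."""

    time_s: np.ndarray
    theta_cumulative: np.ndarray  # fraction of the total fitted change, [0, 1)
    theta_derivative: np.ndarray  # literal finite difference of the fit, per second
    mode: str = "cumulative"

    @property
    def final_cumulative(self) -> float:
        return float(self.theta_cumulative[-1])


def conversion_series(
    series: ResponseSeries,
    t_i_s: float = 0.0,
    t_f_s: float = 960.0,
) -> ConversionSeries:
    """Conversion factor α = (EIR_i − EIR_t)/(EIR_i − EIR_f) pointwise.

    EIR_i is the first measurement at or after ``t_i_s`` and EIR_f the last
    at or before ``t_f_s`` (the paper's 16 min mark by default).  The
    formula is sign-agnostic, so rising (conductance, MIX) and falling
    (low-frequency impedance) responses are treated identically.  α values
    outside [0, 1] are kept (and flagged with a warning); the fit window
    handles them downstream.
    """
    t, v = series.time_s, series.values
    init_candidates = np.nonzero(t >= t_i_s)[0]
    final_candidates = np.nonzero(t <= t_f_s)[0]
    if len(init_candidates) == 0 or len(final_candidates) == 0:
        raise DataError(
            f"series [{t[0]:g}, {t[-1]:g}] s does not span t_i={t_i_s:g}, t_f={t_f_s:g}"
        )
    i0, i1 = init_candidates[0], final_candidates[-1]
    if i1 <= i0:
        raise DataError("final measurement must come after the initial one")
    eir_i, eir_f = float(v[i0]), float(v[i1])
    if eir_i == eir_f:
        raise DegenerateSeriesError("EIR_i equals EIR_f: conversion undefined")
    alpha = (eir_i - v) / (eir_i - eir_f)
    overshoot = (alpha > 1 + 1e-9) | (alpha < -1e-9)
    if np.any(overshoot):
        warnings.warn(
            f"{int(overshoot.sum())} α value(s) outside [0, 1]; "
            "raw values preserved, excluded from the log fit where α ≥ 1",
            stacklevel=2,
        )
    return ConversionSeries(
        time_s=t.copy(),
        alpha=alpha,
        t_initial_s=float(t[i0]),
        t_final_s=float(t[i1]),
        parameter_kind=series.parameter_kind,
        eir_initial=eir_i,
        eir_final=eir_f,
    )


def fit_first_order(
    conv: ConversionSeries,
    window_s: Tuple[float, float] = (30.0, 120.0),
) -> FirstOrderFit:
    """OLS fit of −ln(1−α) on t over the closed window (intercept free).

    Points with α ≥ 1 inside the window (log undefined) are dropped with a
    warning; fewer than two usable points is a fit error.  A constant α
    yields k = 0 with the ``converging`` flag cleared.
    """
    lo, hi = window_s
    if not lo < hi:
        raise DataError(f"window must be ordered, got {window_s}")
    in_window = (conv.time_s >= lo) & (conv.time_s <= hi)
    t = conv.time_s[in_window]
    alpha = conv.alpha[in_window]
    saturated = alpha >= 1.0 - ALPHA_OVERSHOOT_TOL
    if np.any(saturated):
        warnings.warn(
            f"dropping {int(saturated.sum())} in-window point(s) with α ≥ 1",
            stacklevel=2,
        )
    t, alpha = t[~saturated], alpha[~saturated]
    if len(t) < 2:
        raise FitError(
            f"need at least 2 usable points in [{lo:g}, {hi:g}] s, have {len(t)}"
        )
    y = -np.log(1.0 - alpha)
    if np.ptp(y) == 0.0:
        return FirstOrderFit(
            k_per_s=0.0,
            intercept=float(y[0]),
            r_squared=0.0,
            window_s=(lo, hi),
            n_points=len(t),
            converging=False,
        )
    res = stats.linregress(t, y)
    return FirstOrderFit(
        k_per_s=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        window_s=(lo, hi),
        n_points=len(t),
        converging=res.slope > 0,
    )


def hydration_time(k_per_s: float, alpha_target: float = 0.95) -> float:
    """Time (s) to reach the target conversion: t_h = −ln(1 − α)/k."""
    if k_per_s <= 0:
        raise DataError(f"rate constant must be positive, got {k_per_s!r}")
    if not (0 <= alpha_target < 1):
        raise DataError(f"alpha_target must lie in [0, 1), got {alpha_target!r}")
    return -math.log(1.0 - alpha_target) / k_per_s


def round_half_up_minutes(t_s: float) -> int:
    """Whole-minute value reported in the summary tables (round half-up)."""
    return int(math.floor(t_s / 60.0 + 0.5))


def fit_power_law(series: ResponseSeries, t_start_s: float = 30.0) -> PowerLawFit:
    """Nonlinear least squares of Response = a·b^t + c, data at t ≥ t_start only.

    ``b`` is constrained inside (0, 1) through the identity b^t = e^(t ln b)
    with ln b < 0 as the free parameter; the sign of ``a`` is free (negative
    a gives a rising curve approaching c from below).  A constant series
    returns a ≈ 0 with the ``degenerate`` flag set.
    """
    keep = series.time_s >= t_start_s
    t = series.time_s[keep]
    v = series.values[keep]
    if len(t) < 4:
        raise FitError(
            f"power-law fit needs ≥ 4 points at t ≥ {t_start_s:g} s, have {len(t)}"
        )
    scale = np.ptp(v)
    if scale == 0.0:
        return PowerLawFit(
            a=0.0, b=0.5, c=float(v[0]), t_start_s=t_start_s, rmse=0.0, degenerate=True
        )

    def model(tt, a, log_b, c):
        return a * np.exp(log_b * tt) + c

    a0 = v[0] - v[-1]
    if a0 == 0.0:
        a0 = scale
    span = max(t[-1] - t[0], 1.0)
    p0 = (a0, -3.0 / span, float(v[-1]))
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            v,
            p0=p0,
            bounds=([-np.inf, -np.inf, -np.inf], [np.inf, -1e-12, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - exercised only on pathological input
        raise FitError(f"power-law fit did not converge: {exc}") from exc
    a, log_b, c = popt
    resid = v - model(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    degenerate = abs(a) < 1e-9 * max(abs(c), scale, 1.0)
    return PowerLawFit(
        a=float(a),
        b=float(np.exp(log_b)),
        c=float(c),
        t_start_s=t_start_s,
        rmse=rmse,
        degenerate=degenerate,
    )


def degree_of_hydration(
    fit: PowerLawFit,
    t_s: float,
    dt_s: float = 1.0,
) -> HydrationDegree:
    """Degree of hydration on a ``dt_s`` grid from ``t_start`` to ``t_s``.

    Both interpretations are computed: ``theta_derivative`` is the literal
    finite difference of the fitted curve (the change of EIR per Δt = 1 s),
    and ``theta_cumulative`` the fraction of the total fitted change
    completed, 1 − b^(t − t_start), which tends to 1 as t → ∞.
    """
    if fit.degenerate or fit.a == 0.0:
        raise DegenerateSeriesError("fit carries no change: degree undefined")
    if t_s < fit.t_start_s:
        raise DataError(f"t = {t_s:g} s precedes the fit start {fit.t_start_s:g} s")
    grid = fit.t_start_s + np.arange(0.0, t_s - fit.t_start_s + dt_s / 2, dt_s)
    values = fit(grid)
    theta_cum = 1.0 - np.exp(np.log(fit.b) * (grid - fit.t_start_s))
    theta_deriv = np.empty_like(grid)
    theta_deriv[0] = 0.0
    theta_deriv[1:] = np.diff(values) / dt_s
    return HydrationDegree(time_s=grid, theta_cumulative=theta_cum, theta_derivative=theta_deriv)


def degree_at(fit: PowerLawFit, t_s: float) -> float:
    """Cumulative degree of hydration at a single time (closed form)."""
    if fit.degenerate or fit.a == 0.0:
        raise DegenerateSeriesError("fit carries no change: degree undefined")
    if t_s < fit.t_start_s:
        raise DataError(f"t = {t_s:g} s precedes the fit start {fit.t_start_s:g} s")
    return 1.0 - float(np.exp(np.log(fit.b) * (t_s - fit.t_start_s)))


# ---------------------------------------------------------------------------
# Table-style summaries


@dataclass
class GroupStat:
    """Mean ± sample SD of whole-minute times (or whole-percent degrees)."""

    mean: float
    sd: Optional[float]
    n: int

    @property
    def mean_rounded(self) -> int:
        return int(math.floor(self.mean + 0.5))


@dataclass
class KineticsSummary:
    """Per-series hydration times and degrees with grouped means ± SD.

    ``rows`` carries one line per input record with the derived hydration
    time (seconds and whole minutes) and the exclusion status; rows whose
    R² falls below the threshold, or that carry no rate constant, are kept
    but marked excluded with a reason.  Group statistics average the
    whole-minute times (the table-reported quantity) over included rows
    with the sample (n−1) standard deviation.
    """

    rows: pd.DataFrame
    r2_threshold: float
    alpha_target: float

    def _included(self, group: Optional[str] = None, r2_min: Optional[float] = None) -> pd.DataFrame:
        sel = self.rows[~self.rows["excluded"]]
        if group is not None:
            sel = sel[sel["group"] == group]
        if r2_min is not None:
            sel = sel[sel["r_squared"] > r2_min]
        return sel

    @staticmethod
    def _stat(values: pd.Series) -> GroupStat:
        if len(values) == 0:
            raise DataError("no rows left after exclusion")
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else None
        return GroupStat(mean=mean, sd=sd, n=len(values))

    def time_stat(self, group: Optional[str] = None, r2_min: Optional[float] = None) -> GroupStat:
        return self._stat(self._included(group, r2_min)["t_h_min"])

    def degree_stat(self, group: Optional[str] = None, r2_min: Optional[float] = None) -> GroupStat:
        sel = self._included(group, r2_min)["degree_pct"].dropna()
        return self._stat(sel)

    def group_table(self) -> pd.DataFrame:
        """Per-group mean ± SD of the whole-minute hydration times."""
        out = []
        for group in self.rows.loc[~self.rows["excluded"], "group"].unique():
            st = self.time_stat(group=group)
            out.append(
                {"group": group, "mean_t_h_min": st.mean, "sd_t_h_min": st.sd,
                 "mean_t_h_min_rounded": st.mean_rounded, "n": st.n}
            )
        return pd.DataFrame(out)


def summarize_kinetics(
    records: Iterable[Mapping],
    r2_threshold: float = 0.75,
    alpha_target: float = 0.95,
) -> KineticsSummary:
    """Tabulate hydration times and degrees for labelled rate constants.

    Each record is a mapping with keys ``label``, ``group`` (e.g. the
    instrument), ``k_per_s`` and ``r_squared``; ``degree_pct`` is optional.
    Records with a missing/non-positive rate constant, or R² below the
    threshold, are retained with an exclusion reason.
    """
    records = list(records)
    if len(records) == 0:
        raise DataError("summarize_kinetics needs at least one record")
    rows = []
    for rec in records:
        k = rec.get("k_per_s")
        r2 = rec.get("r_squared")
        row = {
            "label": rec.get("label", ""),
            "group": rec.get("group", ""),
            "k_per_s": k,
            "r_squared": r2,
            "degree_pct": rec.get("degree_pct"),
            "t_h_s": np.nan,
            "t_h_min": np.nan,
            "excluded": False,
            "exclusion_reason": "",
        }
        if k is None or (isinstance(k, float) and not np.isfinite(k)):
            row["excluded"] = True
            row["exclusion_reason"] = "no rate constant reported"
        elif k <= 0:
            row["excluded"] = True
            row["exclusion_reason"] = "non-converging (k <= 0)"
        else:
            t_h = hydration_time(float(k), alpha_target)
            row["t_h_s"] = t_h
            row["t_h_min"] = round_half_up_minutes(t_h)
            if r2 is not None and np.isfinite(r2) and r2 < r2_threshold:
                row["excluded"] = True
                row["exclusion_reason"] = f"R² {r2:.3f} below threshold {r2_threshold:g}"
        rows.append(row)
    frame = pd.DataFrame(rows)
    if frame["excluded"].all():
        raise DataError("all records excluded; nothing to summarize")
    return KineticsSummary(rows=frame, r2_threshold=r2_threshold, alpha_target=alpha_target)
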