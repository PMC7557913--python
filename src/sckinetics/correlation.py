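"""Correlation between paired mean response series and replicate pooling tests.

The in vivo / in vitro and cross-method comparisons correlate the *mean*
response curves of two measurement sets with Spearman's rank correlation
(average ranks on ties).  When the two instruments run on different time
grids, the denser set's mean curve is linearly interpolated onto the
sparser grid inside the overlap.  The replicate-pooling question — whether
series from different subjects can be treated as interchangeable
replicates — is answered with two-sided Welch t-tests on per-unit summary
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import ResponseSeries
from .exceptions import DataError, PairingError

PAIRING_RULES = ("shared-timepoints", "interpolate-b-to-a")


@dataclass
class PairedSeries:
    """Two mean response curves aligned on a common time grid."""

    common_time_s: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray
    pairing_rule: str
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self):
        if not (len(self.common_time_s) == len(self.values_a) == len(self.values_b)):
            raise DataError("paired vectors must have equal length")
        if len(self.common_time_s) < 3:
            raise PairingError("pairing needs at least 3 common time points")
        if np.any(np.diff(self.common_time_s) <= 0):
            raise DataError("common times must be strictly increasing")


@dataclass
class CorrelationResult:
    """Spearman ρ over a paired mean series (ρ and n are the headline outputs)."""

    rho: float
    n: int
    pairing_rule: str
    label_a: str
    label_b: str


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Defined as the Pearson correlation of the two rank vectors; undefined
    (an error) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length one-dimensional vectors")
    if len(x) < 3:
        raise DataError("Spearman correlation needs at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("missing or non-finite values are not allowed")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


class DegenerateInputError(DataError):
    """A constant vector makes the rank correlation undefined."""


def pair_mean_series(
    set_a: Sequence[ResponseSeries],
    set_b: Sequence[ResponseSeries],
    rule: str = "interpolate-b-to-a",
    label_a: str = "a",
    label_b: str = "b",
) -> PairedSeries:
    """Pointwise mean within each set, aligned on a common grid.

    Under ``shared-timepoints`` only exactly matching times are kept; under
    ``interpolate-b-to-a`` the set-b mean curve is linearly interpolated
    onto the set-a times inside the overlap of the two spans.
    """
    if rule not in PAIRING_RULES:
        raise DataError(f"pairing rule must be one of {PAIRING_RULES}, got {rule!r}")
    mean_t_a, mean_v_a = _mean_curve(set_a, "set_a")
    mean_t_b, mean_v_b = _mean_curve(set_b, "set_b")

    if rule == "shared-timepoints":
        common, ia, ib = np.intersect1d(mean_t_a, mean_t_b, return_indices=True)
        if len(common) < 3:
            raise PairingError(
                f"only {len(common)} shared time points between the two sets"
            )
        return PairedSeries(common, mean_v_a[ia], mean_v_b[ib], rule, label_a, label_b)

    lo = max(mean_t_a[0], mean_t_b[0])
    hi = min(mean_t_a[-1], mean_t_b[-1])
    keep = (mean_t_a >= lo) & (mean_t_a <= hi)
    if keep.sum() < 3:
        raise PairingError(
            f"overlap [{lo:g}, {hi:g}] s covers only {int(keep.sum())} set-a points"
        )
    t_common = mean_t_a[keep]
    b_interp = np.interp(t_common, mean_t_b, mean_v_b)
    return PairedSeries(t_common, mean_v_a[keep], b_interp, rule, label_a, label_b)


def _mean_curve(series_set: Sequence[ResponseSeries], name: str) -> Tuple[np.ndarray, np.ndarray]:
    if len(series_set) == 0:
        raise DataError(f"{name} is empty")
    t0 = series_set[0].time_s
    for s in series_set[1:]:
        if len(s.time_s) != len(t0) or not np.allclose(s.time_s, t0):
            raise DataError(f"series within {name} must share one time grid")
    values = np.vstack([s.values for s in series_set])
    return t0.copy(), values.mean(axis=0)


def correlate(paired: PairedSeries) -> CorrelationResult:
    """Spearman ρ of the two aligned mean curves."""
    rho = spearman_rho(paired.values_a, paired.values_b)
    return CorrelationResult(
        rho=rho,
        n=len(paired.common_time_s),
        pairing_rule=paired.pairing_rule,
        label_a=paired.label_a,
        label_b=paired.label_b,
    )


class TTestResult(NamedTuple):
    statistic: float
    p_value: float


def pooling_t_test(group1: Sequence[float], group2: Sequence[float]) -> TTestResult:
    """Two-sided Welch (unequal-variance) t-test on per-unit summary values.

    Both groups need at least two values.  The degenerate case of two
    zero-variance groups with equal means returns t = 0, p = 1 by
    convention.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise DataError("each group needs at least 2 values")
    if np.ptp(g1) == 0.0 and np.ptp(g2) == 0.0:
        if g1[0] == g2[0]:
            return TTestResult(0.0, 1.0)
        return TTestResult(np.inf if g1[0] > g2[0] else -np.inf, 0.0)
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return TTestResult(float(res.statistic), float(res.pvalue))
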