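"""Scalar impedance responses derived from frequency sweeps.

An electrical impedance spectrum Z(f) = Z_Re + i Z_Im measured on skin is
reduced to one of three scalar electrical impedance responses (EIR):

* conductance at a target frequency, 10^6 / |Z| in µS (the native output of
  the single-frequency HP probe, emulated for NE at ~315 kHz and 4E at
  ~316 kHz);
* the impedance magnitude |Z| at a low frequency (1 kHz), which tracks the
  resistive barrier properties of the stratum corneum;
* the MIX magnitude index |Z(f_low)| / |Z(f_high)|, sensitive to the balance
  between resistive and capacitive skin properties (20/500 kHz for NE,
  1/10 kHz for the four-electrode Franz cell).

Target frequencies are matched to the instrument grid by nearest neighbour
in log-frequency, with the selected grid point reported so the substitution
stays auditable (e.g. a 300 kHz request resolves to 315.2 kHz on the NE
grid).  The matching tolerance is measured on the log scale,
``|ln(f_selected / f_target)| <= rel_tolerance``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np

from .exceptions import (
    DataError,
    FrequencySelectionError,
    UndefinedPhaseError,
)

PARAMETER_KINDS = ("conductance", "impedance_magnitude", "mix")

_UNITS = {
    "conductance": "uS",
    "impedance_magnitude": "Ohm",
    "mix": "dimensionless",
}


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ImpedanceSpectrum:
    """One frequency sweep at one hydration time point and site.

    Rows are canonicalized (sorted by frequency) on construction; duplicate
    frequencies are rejected so derived responses are invariant under row
    re-ordering of the input.
    """

    frequencies_hz: np.ndarray
    z_re_ohm: np.ndarray
    z_im_ohm: np.ndarray
    time_s: float = 0.0
    method_tag: str = "other"
    replicate_id: str = ""
    site_id: str = ""
    temperature_c: Optional[float] = None

    def __post_init__(self):
        f = _as_float_array(self.frequencies_hz, "frequencies_hz")
        zr = _as_float_array(self.z_re_ohm, "z_re_ohm")
        zi = _as_float_array(self.z_im_ohm, "z_im_ohm")
        if not (len(f) == len(zr) == len(zi)):
            raise DataError(
                "frequencies, z_re and z_im must have equal length "
                f"({len(f)}, {len(zr)}, {len(zi)})"
            )
        if len(f) < 1:
            raise DataError("a spectrum needs at least one frequency")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise DataError("frequencies must be finite and positive")
        if not (np.all(np.isfinite(zr)) and np.all(np.isfinite(zi))):
            raise DataError("impedance entries must be finite")
        order = np.argsort(f, kind="stable")
        f, zr, zi = f[order], zr[order], zi[order]
        if np.any(np.diff(f) <= 0):
            raise DataError("frequencies must be strictly increasing (duplicates found)")
        if self.time_s < 0:
            raise DataError("time_s must be non-negative")
        self.frequencies_hz, self.z_re_ohm, self.z_im_ohm = f, zr, zi

    def __len__(self) -> int:
        return len(self.frequencies_hz)

    @property
    def z_complex(self) -> np.ndarray:
        return self.z_re_ohm + 1j * self.z_im_ohm


@dataclass
class DerivedSpectrum:
    """Magnitude |Z| and phase angle θ (degrees) of a sweep."""

    frequencies_hz: np.ndarray
    magnitude_ohm: np.ndarray
    phase_deg: np.ndarray


@dataclass(frozen=True)
class MixSpec:
    """The low/high frequency pair defining a MIX magnitude index."""

    f_low_hz: float
    f_high_hz: float

    def __post_init__(self):
        if self.f_low_hz <= 0 or self.f_high_hz <= 0:
            raise DataError("MIX frequencies must be positive")
        if self.f_low_hz >= self.f_high_hz:
            raise DataError(
                f"MIX requires f_low < f_high, got {self.f_low_hz} >= {self.f_high_hz}"
            )


MIX_NE = MixSpec(20e3, 500e3)
MIX_4E = MixSpec(1e3, 10e3)


@dataclass
class ResponseSeries:
    """A scalar electrical impedance response EIR(t) over a measurement schedule."""

    time_s: np.ndarray
    values: np.ndarray
    parameter_kind: str
    frequency_spec: Union[float, MixSpec, None] = None
    units: str = ""
    normalized: bool = False
    method_tag: str = "other"
    replicate_id: str = ""
    site_id: str = ""
    temperature_c: Optional[float] = None

    def __post_init__(self):
        t = _as_float_array(self.time_s, "time_s")
        v = _as_float_array(self.values, "values")
        if len(t) != len(v):
            raise DataError("time and value vectors must have equal length")
        if len(t) < 1:
            raise DataError("a response series needs at least one point")
        if np.any(t < 0):
            raise DataError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise DataError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise DataError("response values must be finite")
        if self.parameter_kind not in PARAMETER_KINDS:
            raise DataError(
                f"parameter_kind must be one of {PARAMETER_KINDS}, got {self.parameter_kind!r}"
            )
        if self.parameter_kind in ("conductance", "mix") and np.any(v <= 0):
            raise DataError(f"{self.parameter_kind} values must be positive")
        if not self.units:
            self.units = _UNITS[self.parameter_kind]
        self.time_s, self.values = t, v

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def usable_for_fitting(self) -> bool:
        """Downstream fits need at least two points."""
        return len(self) >= 2


class SelectedValue(NamedTuple):
    """A response value together with the grid frequency actually used."""

    value: float
    frequency_hz: float


def derive_spectrum(spec: ImpedanceSpectrum) -> DerivedSpectrum:
    """Pointwise magnitude |Z| = (Z_Re^2 + Z_Im^2)^0.5 and phase θ = tan⁻¹(Z_Im/Z_Re).

    The phase is restricted to the right half-plane, i.e. θ ∈ (−90°, 90°],
    with Z_Re = Z_Im = 0 an error (undefined phase) rather than 0°.
    """
    zr, zi = spec.z_re_ohm, spec.z_im_ohm
    both_zero = (zr == 0) & (zi == 0)
    if np.any(both_zero):
        f_bad = spec.frequencies_hz[both_zero][0]
        raise UndefinedPhaseError(
            f"phase undefined at {f_bad:g} Hz: Z_Re = Z_Im = 0"
        )
    magnitude = np.hypot(zr, zi)
    phase = np.empty_like(magnitude)
    off_axis = zr != 0
    phase[off_axis] = np.degrees(np.arctan(zi[off_axis] / zr[off_axis]))
    # Z_Re = 0: pure reactance, ±90° by the sign of Z_Im
    phase[~off_axis] = np.sign(zi[~off_axis]) * 90.0
    return DerivedSpectrum(spec.frequencies_hz.copy(), magnitude, phase)


def select_frequency(
    frequencies_hz: np.ndarray,
    f_target_hz: float,
    rel_tolerance: float = 0.05,
) -> int:
    """Index of the grid frequency nearest ``f_target_hz`` in log space.

    Ties (a target exactly between two grid points in log space) break
    toward the lower frequency.  Raises ``FrequencySelectionError`` if the
    target lies outside the grid span or if the nearest point deviates by
    more than ``rel_tolerance`` in log space.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    if f_target_hz <= 0:
        raise FrequencySelectionError("target frequency must be positive")
    if f_target_hz < f[0] or f_target_hz > f[-1]:
        raise FrequencySelectionError(
            f"target {f_target_hz:g} Hz outside grid span [{f[0]:g}, {f[-1]:g}] Hz"
        )
    dist = np.abs(np.log(f) - np.log(f_target_hz))
    # argmin returns the first (= lower-frequency) minimiser on exact ties
    idx = int(np.argmin(dist))
    if dist[idx] > rel_tolerance + 1e-15:
        raise FrequencySelectionError(
            f"nearest grid frequency {f[idx]:g} Hz deviates from target "
            f"{f_target_hz:g} Hz by {dist[idx] * 100:.2f}% in log space "
            f"(tolerance {rel_tolerance * 100:.2f}%)"
        )
    return idx


def conductance_at(
    spec: ImpedanceSpectrum,
    f_target_hz: float,
    rel_tolerance: float = 0.05,
) -> SelectedValue:
    """Conductance 10^6 / |Z| in µS at the grid point log-nearest the target."""
    idx = select_frequency(spec.frequencies_hz, f_target_hz, rel_tolerance)
    magnitude = float(np.hypot(spec.z_re_ohm[idx], spec.z_im_ohm[idx]))
    if magnitude == 0:
        raise DataError(f"|Z| = 0 at {spec.frequencies_hz[idx]:g} Hz")
    return SelectedValue(1e6 / magnitude, float(spec.frequencies_hz[idx]))


def magnitude_at(
    spec: ImpedanceSpectrum,
    f_target_hz: float,
    rel_tolerance: float = 0.05,
) -> SelectedValue:
    """|Z| in Ohm at the grid point log-nearest the target."""
    idx = select_frequency(spec.frequencies_hz, f_target_hz, rel_tolerance)
    magnitude = float(np.hypot(spec.z_re_ohm[idx], spec.z_im_ohm[idx]))
    return SelectedValue(magnitude, float(spec.frequencies_hz[idx]))


def mix_index(
    spec: ImpedanceSpectrum,
    mix: MixSpec,
    rel_tolerance: float = 0.05,
) -> float:
    """MIX = |Z(f_low)| / |Z(f_high)| using log-nearest grid points."""
    low = magnitude_at(spec, mix.f_low_hz, rel_tolerance)
    high = magnitude_at(spec, mix.f_high_hz, rel_tolerance)
    if high.value == 0:
        raise DataError(f"|Z| = 0 at {high.frequency_hz:g} Hz")
    return low.value / high.value


def build_response_series(
    spectra: Sequence[ImpedanceSpectrum],
    kind: str,
    freq_spec: Union[float, MixSpec],
    rel_tolerance: float = 0.05,
) -> ResponseSeries:
    """Assemble a response time series from time-ordered sweeps of one site.

    All sweeps must share method/replicate/site; times must be strictly
    increasing (duplicate or out-of-order time points are an error).
    """
    if len(spectra) == 0:
        raise DataError("no spectra supplied")
    if kind not in PARAMETER_KINDS:
        raise DataError(f"unknown parameter kind {kind!r}")
    tags = {(s.method_tag, s.replicate_id, s.site_id) for s in spectra}
    if len(tags) > 1:
        raise DataError(f"spectra mix replicates/sites/methods: {sorted(tags)}")
    times = np.array([s.time_s for s in spectra], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise DataError("spectra must be in strictly increasing time order")

    if kind == "mix":
        if not isinstance(freq_spec, MixSpec):
            raise DataError("kind='mix' requires a MixSpec frequency specification")
        values = [mix_index(s, freq_spec, rel_tolerance) for s in spectra]
        resolved_spec: Union[float, MixSpec] = freq_spec
    else:
        f_target = float(freq_spec)  # type: ignore[arg-type]
        extract = conductance_at if kind == "conductance" else magnitude_at
        picked = [extract(s, f_target, rel_tolerance) for s in spectra]
        values = [p.value for p in picked]
        resolved_spec = picked[0].frequency_hz  # selected grid frequency, auditable

    first = spectra[0]
    series = ResponseSeries(
        time_s=times,
        values=np.asarray(values, dtype=float),
        parameter_kind=kind,
        frequency_spec=resolved_spec,
        method_tag=first.method_tag,
        replicate_id=first.replicate_id,
        site_id=first.site_id,
        temperature_c=first.temperature_c,
    )
    if not series.usable_for_fitting:
        warnings.warn(
            "single-point response series: unusable for kinetics fitting",
            stacklevel=2,
        )
    return series


def normalize_series(series: ResponseSeries, t_ref_s: float = 30.0) -> ResponseSeries:
    """Divide by the value at the time point nearest ``t_ref_s`` and drop earlier points.

    The reference value is taken at the time point nearest the requested
    reference time (ties break toward the earlier point); all points earlier
    than ``t_ref_s`` are then discarded and the normalized flag is set.
    Normalizing an already-normalized series again is the identity up to the
    dropped leading points.
    """
    t = series.time_s
    if t_ref_s < t[0] or t_ref_s > t[-1]:
        raise DataError(
            f"reference time {t_ref_s:g} s outside series span [{t[0]:g}, {t[-1]:g}] s"
        )
    dist = np.abs(t - t_ref_s)
    ref_idx = int(np.argmin(dist))  # first minimiser = earlier point on ties
    ref = series.values[ref_idx]
    if ref == 0:
        raise DataError("reference value is zero; cannot normalize")
    keep = t >= t_ref_s
    return replace(
        series,
        time_s=t[keep],
        values=series.values[keep] / ref,
        normalized=True,
        units="relative",
    )
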