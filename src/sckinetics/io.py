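"""CSV dialects for spectra and response series.

Long-format, UTF-8, comma-separated with a header row:

* spectra: ``method,replicate_id,site_id,temperature_c,time_s,frequency_hz,
  z_re_ohm,z_im_ohm`` — one row per (time, frequency);
* series: ``method,replicate_id,site_id,temperature_c,time_s,parameter,
  frequency_low_hz,frequency_high_hz,value,units,normalized`` —
  ``frequency_high_hz`` is empty unless the parameter is the MIX index.

Write∘read is the identity on values within decimal-text precision.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .core import ImpedanceSpectrum, MixSpec, ResponseSeries
from .exceptions import DataError, SchemaError

SPECTRA_COLUMNS = [
    "method",
    "replicate_id",
    "site_id",
    "temperature_c",
    "time_s",
    "frequency_hz",
    "z_re_ohm",
    "z_im_ohm",
]

SERIES_COLUMNS = [
    "method",
    "replicate_id",
    "site_id",
    "temperature_c",
    "time_s",
    "parameter",
    "frequency_low_hz",
    "frequency_high_hz",
    "value",
    "units",
    "normalized",
]


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    for column in required:
        if column not in frame.columns:
            raise SchemaError(f"{path}: missing required column {column!r}")


def write_spectra(spectra: Iterable[ImpedanceSpectrum], path) -> None:
    rows = []
    for spec in spectra:
        for f, zr, zi in zip(spec.frequencies_hz, spec.z_re_ohm, spec.z_im_ohm):
            rows.append(
                (
                    spec.method_tag,
                    spec.replicate_id,
                    spec.site_id,
                    spec.temperature_c if spec.temperature_c is not None else np.nan,
                    spec.time_s,
                    f,
                    zr,
                    zi,
                )
            )
    pd.DataFrame(rows, columns=SPECTRA_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_spectra(path) -> List[ImpedanceSpectrum]:
    """Read a spectra CSV, grouping rows into sweeps by (method, replicate, site, time)."""
    frame = pd.read_csv(path)
    _require_columns(frame, SPECTRA_COLUMNS, path)
    dupes = frame.duplicated(subset=["method", "replicate_id", "site_id", "time_s", "frequency_hz"])
    if dupes.any():
        first = frame[dupes].iloc[0]
        raise DataError(
            f"{path}: duplicated (time, frequency) row at t={first.time_s:g} s, "
            f"f={first.frequency_hz:g} Hz"
        )
    spectra = []
    keys = ["method", "replicate_id", "site_id", "time_s"]
    for (method, rep, site, t), group in frame.groupby(keys, sort=True):
        temp = group["temperature_c"].iloc[0]
        spectra.append(
            ImpedanceSpectrum(
                frequencies_hz=group["frequency_hz"].to_numpy(),
                z_re_ohm=group["z_re_ohm"].to_numpy(),
                z_im_ohm=group["z_im_ohm"].to_numpy(),
                time_s=float(t),
                method_tag=str(method),
                replicate_id=str(rep),
                site_id=str(site),
                temperature_c=None if pd.isna(temp) else float(temp),
            )
        )
    return spectra


def write_series(series_list: Iterable[ResponseSeries], path) -> None:
    rows = []
    for series in series_list:
        if isinstance(series.frequency_spec, MixSpec):
            f_low, f_high = series.frequency_spec.f_low_hz, series.frequency_spec.f_high_hz
        elif series.frequency_spec is None:
            f_low, f_high = np.nan, np.nan
        else:
            f_low, f_high = float(series.frequency_spec), np.nan
        for t, v in zip(series.time_s, series.values):
            rows.append(
                (
                    series.method_tag,
                    series.replicate_id,
                    series.site_id,
                    series.temperature_c if series.temperature_c is not None else np.nan,
                    t,
                    series.parameter_kind,
                    f_low,
                    f_high,
                    v,
                    series.units,
                    series.normalized,
                )
            )
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_series(path) -> List[ResponseSeries]:
    """Read a series CSV, one ResponseSeries per (method, replicate, site, parameter)."""
    frame = pd.read_csv(path)
    _require_columns(frame, SERIES_COLUMNS, path)
    out = []
    keys = ["method", "replicate_id", "site_id", "parameter"]
    for (method, rep, site, parameter), group in frame.groupby(keys, sort=True):
        group = group.sort_values("time_s", kind="stable")
        if group["time_s"].duplicated().any():
            raise DataError(f"{path}: duplicate time points in series {method}/{rep}/{site}")
        f_low = group["frequency_low_hz"].iloc[0]
        f_high = group["frequency_high_hz"].iloc[0]
        if parameter == "mix":
            freq_spec: Union[float, MixSpec, None] = MixSpec(float(f_low), float(f_high))
        else:
            freq_spec = None if pd.isna(f_low) else float(f_low)
        temp = group["temperature_c"].iloc[0]
        out.append(
            ResponseSeries(
                time_s=group["time_s"].to_numpy(),
                values=group["value"].to_numpy(),
                parameter_kind=str(parameter),
                frequency_spec=freq_spec,
                units=str(group["units"].iloc[0]),
                normalized=bool(group["normalized"].iloc[0]),
                method_tag=str(method),
                replicate_id=str(rep),
                site_id=str(site),
                temperature_c=None if pd.isna(temp) else float(temp),
            )
        )
    return out
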