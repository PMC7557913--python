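"""Published rate-constant tables bundled as structured fixtures.

Two summary tables of first-order hydration kinetics are shipped verbatim:

* the initial-stage table (room temperature): rate constant k (s⁻¹),
  hydration time to 95% conversion in whole minutes, R² of the −ln(1−α)
  regression, and the degree of hydration at t_h, for each of the
  method/parameter/setting combinations — with the three NE in vitro rows
  excluded (cartilage-disturbed data, marked unusable);
* the temperature table: the same quantities for the four-electrode Franz
  cell at 12–72 °C for the conductance, 1 kHz and MIX responses, where
  some rows used a shortened 0–6 min conversion window and some
  temperature/parameter combinations were too noisy to regress.

Each accessor builds a fresh DataFrame so the fixtures are immutable across
calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_TABLE2_ROWS = [
    # label, group(method), context, parameter, k_per_s, t_printed_min, r_squared, degree_pct, usable
    ("HP conductance in vivo", "HP", "in vivo", "conductance", 0.0136, 4, 0.991, 97, True),
    ("HP conductance in vitro", "HP", "in vitro", "conductance", 0.0087, 6, 0.993, 95, True),
    ("NE conductance in vivo", "NE", "in vivo", "conductance", 0.0051, 10, 0.831, 96, True),
    ("NE conductance in vitro", "NE", "in vitro", "conductance", np.nan, np.nan, np.nan, np.nan, False),
    ("NE MIX in vivo", "NE", "in vivo", "mix", 0.0095, 5, 0.997, 91, True),
    ("NE MIX in vitro", "NE", "in vitro", "mix", np.nan, np.nan, np.nan, np.nan, False),
    ("NE 1 kHz in vivo", "NE", "in vivo", "impedance_magnitude", 0.0062, 8, 0.764, 93, True),
    ("NE 1 kHz in vitro", "NE", "in vitro", "impedance_magnitude", np.nan, np.nan, np.nan, np.nan, False),
    ("4E conductance in vitro", "4E", "in vitro", "conductance", 0.0049, 10, 0.963, 88, True),
    ("4E MIX in vitro", "4E", "in vitro", "mix", 0.0034, 15, 0.904, 97, True),
    ("4E 1 kHz in vitro", "4E", "in vitro", "impedance_magnitude", 0.0080, 6, 0.964, 88, True),
]

_TABLE3_ROWS = [
    # temperature_c, parameter, k_per_s, t_printed_min, r_squared, short_window(* = 0-6 min), usable
    (12, "conductance", 0.0057, 9, 0.985, False, True),
    (12, "impedance_magnitude", 0.0085, 6, 0.998, False, True),
    (12, "mix", np.nan, np.nan, np.nan, False, False),
    (22, "conductance", 0.0048, 11, 0.962, False, True),
    (22, "impedance_magnitude", 0.0080, 6, 0.964, False, True),
    (22, "mix", 0.0034, 15, 0.904, False, True),
    (32, "conductance", 0.0054, 9, 0.996, False, True),
    (32, "impedance_magnitude", 0.0072, 7, 0.990, False, True),
    (32, "mix", 0.0027, 18, 0.836, False, True),
    (42, "conductance", 0.0044, 12, 0.993, False, True),
    (42, "impedance_magnitude", 0.0074, 7, 0.999, False, True),
    (42, "mix", 0.0033, 15, 0.997, True, True),
    (52, "conductance", 0.0034, 15, 0.946, False, True),
    (52, "impedance_magnitude", np.nan, np.nan, np.nan, False, False),
    (52, "mix", 0.0026, 19, 0.903, True, True),
    (72, "conductance", 0.0046, 11, 0.978, False, True),
    (72, "impedance_magnitude", np.nan, np.nan, np.nan, False, False),
    (72, "mix", 0.0025, 20, 0.984, True, True),
]


def initial_kinetics_table() -> pd.DataFrame:
    """The room-temperature first-order kinetics summary (11 rows, 8 usable)."""
    return pd.DataFrame(
        _TABLE2_ROWS,
        columns=[
            "label",
            "group",
            "context",
            "parameter",
            "k_per_s",
            "t_printed_min",
            "r_squared",
            "degree_pct",
            "usable",
        ],
    )


def temperature_kinetics_table() -> pd.DataFrame:
    """The per-temperature 4E kinetics summary (6 temperatures × 3 parameters)."""
    return pd.DataFrame(
        _TABLE3_ROWS,
        columns=[
            "temperature_c",
            "parameter",
            "k_per_s",
            "t_printed_min",
            "r_squared",
            "short_window",
            "usable",
        ],
    )


def initial_kinetics_records() -> list:
    """Usable initial-table rows as records for ``summarize_kinetics``."""
    table = initial_kinetics_table()
    usable = table[table["usable"]]
    return [
        {
            "label": row.label,
            "group": row.group,
            "k_per_s": row.k_per_s,
            "r_squared": row.r_squared,
            "degree_pct": row.degree_pct,
        }
        for row in usable.itertuples()
    ]


def temperature_kinetics_records(parameter: str) -> list:
    """Usable temperature-table rows of one parameter as summary records."""
    table = temperature_kinetics_table()
    usable = table[table["usable"] & (table["parameter"] == parameter)]
    if len(usable) == 0:
        raise ValueError(f"no usable rows for parameter {parameter!r}")
    return [
        {
            "label": f"{parameter}@{row.temperature_c:g}C",
            "group": parameter,
            "k_per_s": row.k_per_s,
            "r_squared": row.r_squared,
        }
        for row in usable.itertuples()
    ]
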