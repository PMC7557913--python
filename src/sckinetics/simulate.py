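"""Instrument-faithful synthetic impedance data from an evolving skin circuit.

The stratum corneum is modelled as a parallel R||CPE block (resistance
``r_sc``, constant-phase element built on capacitance ``c_sc`` with exponent
``p_cpe``) in series with a solution/deep-tissue resistance ``r_sol``:

    Z(ω) = r_sol + r_sc / (1 + (j ω r_sc c_sc)^p_cpe)

Hydration is a two-stage trajectory of the circuit elements:

* stage 1 (first-order, rate ``k_stage1_per_s``): ``r_sc`` relaxes
  exponentially from its initial value down to a plateau while ``c_sc``
  rises to its plateau — the fast filling of superficial voids with
  electrolyte;
* stage 2 (after ``t_break_s``): slow linear fractional drift of both
  elements, the structural-relaxation stage.

The stage-1 defaults (r_sc 300→140 kΩ, c_sc 0.1→0.65 nF) place the RC
relaxation near 5 kHz so that 1 kHz probes the resistive branch, and make
the fractional capacitance growth exceed the resistance drop so the MIX
index — an increasing function of the r_sc·c_sc product — rises on
hydration and stays monotone (the product of the two same-rate exponentials
is monotone only when the capacitance growth fraction exceeds the
resistance drop fraction).  MIX is flat in stage 2 whenever the two linear
drift rates are equal.  The low-frequency end of the sweep (10 Hz) reads
r_sc almost directly (the CPE branch is open there), so the measured
DC-limit resistance inherits the trajectory's first-order kinetics.

Three instrument designs are provided: HP (single 300 kHz conductance,
12 time points over 16 min), NE (35 log-spaced frequencies 1 kHz–2.5 MHz,
same schedule) and 4E (10 Hz–1 MHz at 4 frequencies/decade, 60 scans over
3 h 10 min with a geometrically coarsening interval pattern).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .core import ImpedanceSpectrum, MixSpec, ResponseSeries, MIX_NE, MIX_4E
from .exceptions import DataError

# ---------------------------------------------------------------------------
# circuit


@dataclass(frozen=True)
class CircuitParams:
    """Snapshot of the skin equivalent circuit at one instant."""

    r_sol_ohm: float
    r_sc_ohm: float
    c_sc_farad: float
    p_cpe: float = 0.85

    def __post_init__(self):
        if self.r_sol_ohm <= 0 or self.r_sc_ohm <= 0 or self.c_sc_farad <= 0:
            raise DataError("circuit elements must be positive")
        if not (0 < self.p_cpe <= 1):
            raise DataError("p_cpe must lie in (0, 1]")


def circuit_impedance(params: CircuitParams, f_hz) -> np.ndarray:
    """Complex impedance of the series-R + parallel R||CPE circuit.

    Vectorised over frequency.  Limits: |Z| → r_sol + r_sc as f → 0 and
    |Z| → r_sol as f → ∞; at the relaxation frequency ω = 1/(r_sc c_sc)
    with p_cpe = 1 the SC branch contributes r_sc (1 − j)/2.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f <= 0):
        raise DataError("frequencies must be positive")
    omega = 2 * np.pi * f
    x = (1j * omega * params.r_sc_ohm * params.c_sc_farad) ** params.p_cpe
    return params.r_sol_ohm + params.r_sc_ohm / (1 + x)


# ---------------------------------------------------------------------------
# hydration trajectory


@dataclass(frozen=True)
class HydrationTrajectory:
    """Ground-truth two-stage evolution of the circuit elements."""

    k_stage1_per_s: float = 0.005
    r_sc_initial_ohm: float = 300e3
    r_sc_plateau_ohm: float = 140e3
    c_sc_initial_farad: float = 0.1e-9
    c_sc_plateau_farad: float = 0.65e-9
    t_break_s: float = 3600.0
    r_slope_per_s: float = 2.0e-5  # fractional decrease of r_sc per second in stage 2
    c_slope_per_s: float = 2.0e-5  # fractional increase of c_sc per second in stage 2
    temperature_c: float = 22.0
    r_sol_ohm: float = 1e3
    p_cpe: float = 0.85

    def __post_init__(self):
        if self.k_stage1_per_s <= 0:
            raise DataError("k_stage1_per_s must be positive")
        if not (self.r_sc_initial_ohm > self.r_sc_plateau_ohm > 0):
            raise DataError("need r_sc_initial > r_sc_plateau > 0")
        if self.c_sc_plateau_farad < self.c_sc_initial_farad:
            raise DataError("need c_sc_plateau >= c_sc_initial")
        if self.t_break_s <= 0:
            raise DataError("t_break_s must be positive")
        if self.r_slope_per_s < 0 or self.c_slope_per_s < 0:
            raise DataError("stage-2 fractional rates must be non-negative")


def trajectory_at(traj: HydrationTrajectory, t_s: float) -> CircuitParams:
    """Circuit parameters at elapsed hydration time ``t_s``.

    Stage 1 (t ≤ t_break): exponential approach to the plateau at rate k.
    Stage 2 (t > t_break): linear fractional drift continuing from the
    break-point values; continuous at the break by construction.
    """
    if t_s < 0:
        raise DataError("time must be non-negative")
    k = traj.k_stage1_per_s

    def _stage1(t):
        decay = np.exp(-k * t)
        r = traj.r_sc_plateau_ohm + (traj.r_sc_initial_ohm - traj.r_sc_plateau_ohm) * decay
        c = traj.c_sc_plateau_farad + (traj.c_sc_initial_farad - traj.c_sc_plateau_farad) * decay
        return r, c

    if t_s <= traj.t_break_s:
        r, c = _stage1(t_s)
    else:
        r_b, c_b = _stage1(traj.t_break_s)
        tau = t_s - traj.t_break_s
        r = r_b * max(1.0 - traj.r_slope_per_s * tau, 1e-6)
        c = c_b * (1.0 + traj.c_slope_per_s * tau)
    return CircuitParams(traj.r_sol_ohm, r, c, traj.p_cpe)


# ---------------------------------------------------------------------------
# temperature presets for the stage-2 drift

_PRESET_TEMPS = np.array([12.0, 22.0, 32.0, 42.0, 52.0, 72.0])
# measured-rate multipliers relative to the 22 °C baseline
_COND_MULT = np.array([1.0, 1.0, 1.0, 1.0, 2.5, 5.0])  # flat 12-42, up at 52, more at 72
_RES_MULT = np.array([1.0, 1.0, 1.6, 2.2, 2.8, 6.0])  # constant 12-22, collinear 32/42/52


def temperature_preset(temperature_c: float, p_cpe: float = 0.85) -> Dict[str, float]:
    """Stage-2 slope multipliers for the three measured parameters.

    Returns the multipliers (relative to the 22 °C baseline) that the
    generator applies to the stage-2 drift: ``conductance`` reproduces the
    flat-then-increasing pattern, ``resistance`` the linearly growing
    decline rate above 22 °C, and ``mix`` the drift gap between the
    capacitance and resistance rates (zero at the baseline where MIX is
    flat, negative at 72 °C where MIX declines).  Temperatures between the
    tabulated points are linearly interpolated; outside [0, 100] °C is a
    range error.
    """
    t = float(temperature_c)
    if not (0.0 <= t <= 100.0):
        raise DataError(f"temperature {t:g} °C outside the supported range [0, 100]")
    cond = float(np.interp(t, _PRESET_TEMPS, _COND_MULT))
    res = float(np.interp(t, _PRESET_TEMPS, _RES_MULT))
    # conductance at the ~316 kHz read-out scales like r_sc^(1-p) c_sc^-p, so
    # the capacitance-drift multiplier follows from the conductance target:
    cap = (cond - (1.0 - p_cpe) * res) / p_cpe
    return {"conductance": cond, "resistance": res, "mix": cap - res}


def trajectory_for_temperature(
    temperature_c: float,
    base: Optional[HydrationTrajectory] = None,
) -> HydrationTrajectory:
    """Trajectory whose stage-2 drift follows the temperature preset."""
    base = base if base is not None else HydrationTrajectory()
    mult = temperature_preset(temperature_c, base.p_cpe)
    r_slope = base.r_slope_per_s * mult["resistance"]
    c_slope = base.c_slope_per_s * (mult["resistance"] + mult["mix"])
    return replace(
        base,
        temperature_c=float(temperature_c),
        r_slope_per_s=r_slope,
        c_slope_per_s=max(c_slope, 0.0),
    )


# ---------------------------------------------------------------------------
# instrument designs


def _schedule_12pt() -> np.ndarray:
    # 12 time points between 0 and 16 min, denser early where the response
    # changes fastest (the exact in vivo grid is configurable)
    return np.array([0, 30, 60, 90, 120, 180, 240, 360, 480, 600, 780, 960], dtype=float)


def _schedule_4e() -> np.ndarray:
    # 60 scans: 20 s intervals (scans 1-20), 1 min (21-30), 2.5 min (31-40),
    # 5 min (41-50), 10 min (51-60); ~3 h 10 min in total
    intervals = np.concatenate(
        [np.full(19, 20.0), np.full(10, 60.0), np.full(10, 150.0), np.full(10, 300.0), np.full(10, 600.0)]
    )
    return np.concatenate([[0.0], np.cumsum(intervals)])


@dataclass(frozen=True)
class InstrumentDesign:
    """Frequency grid, measurement schedule and reported parameters of one instrument."""

    name: str
    frequencies_hz: np.ndarray
    schedule_s: np.ndarray
    conductance_f_hz: float = 300e3
    conductance_rel_tol: float = 0.05
    low_f_hz: Optional[float] = 1e3
    mix: Optional[MixSpec] = None

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        s = np.asarray(self.schedule_s, dtype=float)
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise DataError("frequency grid must be positive and strictly increasing")
        if len(s) < 1 or np.any(np.diff(s) <= 0) or s[0] < 0:
            raise DataError("schedule must be non-negative and strictly increasing")
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "schedule_s", s)


def hp_design(schedule_s: Optional[Sequence[float]] = None) -> InstrumentDesign:
    """DermaLab hydration probe: single-frequency 300 kHz conductance."""
    return InstrumentDesign(
        name="HP",
        frequencies_hz=np.array([300e3]),
        schedule_s=np.asarray(schedule_s, dtype=float) if schedule_s is not None else _schedule_12pt(),
        low_f_hz=None,
        mix=None,
    )


def ne_design(schedule_s: Optional[Sequence[float]] = None) -> InstrumentDesign:
    """Nevisense: 35 log-spaced frequencies, 1 kHz – 2.5 MHz."""
    return InstrumentDesign(
        name="NE",
        frequencies_hz=np.geomspace(1e3, 2.5e6, 35),
        schedule_s=np.asarray(schedule_s, dtype=float) if schedule_s is not None else _schedule_12pt(),
        mix=MIX_NE,
    )


def franz_cell_design(schedule_s: Optional[Sequence[float]] = None) -> InstrumentDesign:
    """Four-electrode Franz cell: 10^(1+k/4) Hz for k = 0..20, 60-scan schedule.

    The quarter-decade grid has no point at the nominal 300 kHz conductance
    frequency closer than 10^5.5 = 316.2 kHz (5.27% away in log space), so
    the matching tolerance is widened accordingly.
    """
    return InstrumentDesign(
        name="4E",
        frequencies_hz=10.0 ** (1 + np.arange(21) / 4.0),
        schedule_s=np.asarray(schedule_s, dtype=float) if schedule_s is not None else _schedule_4e(),
        conductance_rel_tol=0.06,
        mix=MIX_4E,
    )


# ---------------------------------------------------------------------------
# noise and the experiment generator


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise plus replicate-level biological variability.

    ``magnitude_cv`` is multiplicative on |Z| per (time, frequency) point,
    ``phase_sd_deg`` additive on the phase, and ``replicate_cv`` is the
    coefficient of variation of a truncated log-normal scale factor applied
    to the whole r_sc trajectory (initial and plateau jointly, a membrane
    thickness/area effect) across replicates — the substantial membrane-to-
    membrane variation that motivates normalizing 4E data.
    """

    magnitude_cv: float = 0.02
    phase_sd_deg: float = 1.0
    replicate_cv: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if min(self.magnitude_cv, self.phase_sd_deg, self.replicate_cv) < 0:
            raise DataError("noise parameters must be non-negative")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseModel":
        """Zero-noise model: deterministic simulation given the trajectory."""
        return cls(magnitude_cv=0.0, phase_sd_deg=0.0, replicate_cv=0.0, seed=seed)


@dataclass
class SimulatedDataset:
    """Spectra (NE, 4E) or conductance series (HP) plus a provenance manifest."""

    design: InstrumentDesign
    spectra: List[ImpedanceSpectrum] = field(default_factory=list)
    series: List[ResponseSeries] = field(default_factory=list)
    manifest: Dict = field(default_factory=dict)

    def replicate_ids(self) -> List[str]:
        items = self.spectra if self.spectra else self.series
        seen: List[str] = []
        for item in items:
            if item.replicate_id not in seen:
                seen.append(item.replicate_id)
        return seen

    def replicate_spectra(self, replicate_id: str) -> List[ImpedanceSpectrum]:
        return [s for s in self.spectra if s.replicate_id == replicate_id]


def _replicate_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    # truncate extreme draws so the scaled r_sc_initial stays above the plateau
    return np.clip(factors, 0.45, 2.2)


def simulate_experiment(
    design: InstrumentDesign,
    traj: HydrationTrajectory,
    n_replicates: int = 5,
    noise: Optional[NoiseModel] = None,
) -> SimulatedDataset:
    """Simulate one hydration experiment on ``n_replicates`` skin sites.

    Stream order of the single seeded generator is fixed: replicate scale
    factors first, then, per replicate and per scheduled time, one magnitude
    noise vector and one phase noise vector over the frequency grid — so a
    given seed yields a byte-identical dataset.
    """
    if n_replicates < 1:
        raise DataError("n_replicates must be at least 1")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(noise.seed)
    factors = _replicate_factors(rng, n_replicates, noise.replicate_cv)

    dataset = SimulatedDataset(design=design)
    for i in range(n_replicates):
        rep_id = f"rep{i + 1:02d}"
        # the biological scale factor multiplies the whole resistance curve
        # (membrane thickness/area effect), keeping the trajectory shape valid
        rep_traj = replace(
            traj,
            r_sc_initial_ohm=traj.r_sc_initial_ohm * factors[i],
            r_sc_plateau_ohm=traj.r_sc_plateau_ohm * factors[i],
        )
        rep_values = []  # HP conductance accumulator
        for t in design.schedule_s:
            params = trajectory_at(rep_traj, float(t))
            z = circuit_impedance(params, design.frequencies_hz)
            mag = np.abs(z)
            phase = np.angle(z)
            mag_noise = rng.standard_normal(len(mag))
            phase_noise = rng.standard_normal(len(mag))
            mag = mag * np.clip(1.0 + noise.magnitude_cv * mag_noise, 0.05, None)
            phase = phase + np.radians(noise.phase_sd_deg) * phase_noise
            if design.name == "HP":
                rep_values.append(1e6 / mag[0])
            else:
                dataset.spectra.append(
                    ImpedanceSpectrum(
                        frequencies_hz=design.frequencies_hz.copy(),
                        z_re_ohm=mag * np.cos(phase),
                        z_im_ohm=mag * np.sin(phase),
                        time_s=float(t),
                        method_tag=design.name,
                        replicate_id=rep_id,
                        site_id="site1",
                        temperature_c=traj.temperature_c,
                    )
                )
        if design.name == "HP":
            dataset.series.append(
                ResponseSeries(
                    time_s=design.schedule_s.copy(),
                    values=np.asarray(rep_values),
                    parameter_kind="conductance",
                    frequency_spec=design.conductance_f_hz,
                    method_tag="HP",
                    replicate_id=rep_id,
                    site_id="site1",
                    temperature_c=traj.temperature_c,
                )
            )

    dataset.manifest = {
        "design": {
            "name": design.name,
            "n_frequencies": int(len(design.frequencies_hz)),
            "f_min_hz": float(design.frequencies_hz[0]),
            "f_max_hz": float(design.frequencies_hz[-1]),
            "n_times": int(len(design.schedule_s)),
            "t_max_s": float(design.schedule_s[-1]),
        },
        "trajectory": dataclasses.asdict(traj),
        "noise": dataclasses.asdict(noise),
        "n_replicates": n_replicates,
        "seed": noise.seed,
    }
    return dataset
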