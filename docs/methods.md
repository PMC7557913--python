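# Methods

## Scalar responses from impedance sweeps

A measurement is a frequency sweep Z(f) = Z_Re + i·Z_Im. Derived pointwise
quantities are the magnitude |Z| = (Z_Re² + Z_Im²)^½ and the phase
θ = tan⁻¹(Z_Im/Z_Re) in degrees, restricted to the right half-plane
(θ ∈ (−90°, 90°]); Z_Re = Z_Im = 0 is an undefined-phase error rather than
0°. Three scalar electrical impedance responses (EIR) are tracked over
hydration time:

| response | definition | units | direction on hydration |
|---|---|---|---|
| conductance | 10⁶/\|Z(f*)\| | µS | rises |
| low-frequency magnitude | \|Z(1 kHz)\| | Ω | falls |
| MIX index | \|Z(f_low)\|/\|Z(f_high)\| | — | rises |

Target frequencies are resolved to the instrument grid by nearest neighbour
in log-frequency, with ties broken toward the lower frequency and the
selected frequency reported in the series metadata (the substitution must
stay auditable: a 300 kHz request resolves to 315.2 kHz on the 35-point NE
grid and 316.2 kHz on the quarter-decade 4E grid). The matching tolerance
is measured on the log scale, |ln(f_sel/f_target)| ≤ rel_tolerance, default
0.05 (0.06 for the coarser 4E grid). MIX pairs are 20/500 kHz for NE and
1/10 kHz for 4E. Whether the original instruments interpolated rather than
taking the literal nearest grid point is unknown; nearest-point is the
implemented interpretation and the selected frequency is always exported.

Series are normalized by the value at the time point nearest 30 s (ties
toward the earlier point), dropping earlier points — the first 30 s carry
an electrode-contact transient, and the instruments produce incomparable
absolute scales.

## Initial-stage kinetics

The conversion factor α(t) = (EIR_i − EIR_t)/(EIR_i − EIR_f) maps any
monotone response onto [0, 1]; EIR_i is the first measurement (t = 0) and
EIR_f the last measurement at or before the configurable protocol end
(960 s by default). The formula is sign-agnostic, so rising and falling
responses are treated identically. Under first-order decelerating
kinetics −ln(1 − α) = k·t; k is estimated by ordinary least squares over
the closed 30–120 s window with a *free* intercept — the early contact
transient and the finite final measurement both displace the line without
changing its slope, so the slope is the robust quantity (whether the
original regressions were forced through the origin is not stated; the free
intercept reproduces every published minute cell). In-window points with
α ≥ 1 − 1e−12 are dropped with a warning before the log transform; out-of-
range α elsewhere is preserved raw and only warned about. A constant α
yields k = 0 with a non-converging flag.

The hydration time to a target conversion (default α = 0.95) is
t_h = −ln(1 − α)/k, reported in whole minutes with round-half-up — the
convention that reproduces all fourteen published minute cells from their
printed rate constants. Group summaries average the whole-minute values
(the tabulated quantity) with the sample (n−1) standard deviation; averaging
unrounded times changes two of the published section means, so the rounded
convention is the one the source tables used.

Smooth response curves are fitted as EIR = a·bᵗ + c with b ∈ (0, 1)
enforced through the substitution bᵗ = e^(t·ln b) (free parameter ln b < 0,
`scipy.optimize.curve_fit`), using only t ≥ 30 s and requiring at least
four points. The sign of a is free: a < 0 gives a rising curve approaching
the asymptote c. A constant series returns a ≈ 0 with a degenerate flag.

Two readings of the degree of hydration θ_h are computed from such a fit:

- **derivative** (literal): the finite difference of the fitted curve on a
  1 s grid, a·b^(t−1)·(b−1)/Δt — a rate in s⁻¹;
- **cumulative** (reporting default): the fraction of the total fitted
  change completed, |f(t_start) − f(t)|/|f(t_start) − c| = 1 − b^(t−t_start).

The published θ_h values sit in the 88–97% range at t_h, which only the
cumulative reading produces (the derivative is numerically tiny there), so
cumulative is the default reporting mode; both are always computed. For a
pure-exponential fit the cumulative degree is algebraically the conversion
α with EIR_f replaced by the asymptote, and it equals 0.95 exactly at
t_start + t_h(0.95).

## Second stage and temperature

After roughly 60 min the responses drift linearly. The rate of change ∆
(s⁻¹) is the OLS slope of the normalized response over the closed
60–150 min window (≥ 3 points; a constant window returns ∆ = 0 with R²
reported as 0). The 60–150 min window follows the figure-level definition,
which is stated twice; a 60–180 min variant appears once in prose and the
window is configurable. Per-(temperature, parameter) profiles report
mean ± SEM, with SEM missing (not 0) for single-member groups. The
initial-stage analysis is re-run per temperature with a configurable
conversion window: 0–16 min by default, 0–6 min for responses that deviate
at longer times (the starred rows of the published temperature table).

## Correlations and pooling

Paired mean curves: within each measurement set the replicate series
(sharing one time grid) are averaged pointwise; across sets, either exactly
matching time points are kept (`shared-timepoints`) or the second set's
mean curve is linearly interpolated onto the sparser first grid inside the
overlap (`interpolate-b-to-a`, the default — needed because the 4E scan
schedule shares no grid with the 12-point protocol). Spearman ρ uses
average ranks on ties; a constant vector is an undefined-correlation error.
ρ and n are the headline outputs (correlation p-values are deliberately not
reported). The replicate-pooling question uses the Welch (unequal-variance)
two-sided t-test; the published analysis says only "two-sided t-tests" and
Welch is the safer default. Two zero-variance groups with equal means
return t = 0, p = 1 by convention.

## The synthetic-data generator

**Circuit.** Z(ω) = r_sol + r_sc/(1 + (jω·r_sc·c_sc)^p), a solution/deep-
tissue series resistance plus the SC as a resistor parallel to a
constant-phase element (p = 1 is an ideal capacitor). Limits: |Z| → r_sol +
r_sc as ω → 0 and → r_sol as ω → ∞; at ω = 1/(r_sc·c_sc) with p = 1 the SC
branch contributes exactly r_sc(1 − j)/2. |Z| is strictly decreasing in
frequency, so every simulated MIX value exceeds 1.

**Trajectory.** Stage 1: r_sc relaxes exponentially (rate k_stage1) from
its initial value to a plateau while c_sc rises to its plateau; stage 2
(after t_break = 3600 s): linear fractional drift of both elements,
continuous at the break. Defaults: r_sol = 1 kΩ, p = 0.85, r_sc
300 → 140 kΩ, c_sc 0.1 → 0.65 nF, k = 0.005 s⁻¹, drift 2×10⁻⁵ s⁻¹ on both
elements. Three constraints fixed these choices at design time:

1. *Regime.* The initial relaxation frequency 1/(2π·r_sc·c_sc) ≈ 5 kHz puts
   1 kHz in the resistive branch (|Z(1 kHz)| tracks r_sc) and 10 kHz+ in
   the dispersive branch — the regime in which the MIX index is an
   *increasing* function of the r_sc·c_sc product and therefore rises on
   hydration, as observed. Much larger capacitances push the relaxation
   below every analysis frequency and invert the MIX response.
2. *Monotonicity.* With both elements relaxing at the same rate, the
   product r_sc·c_sc is a parabola in e^(−kt); it is monotone (up to a
   ~2% excursion) only when the fractional capacitance growth (×6.5)
   exceeds the fractional resistance drop (×2.14). This keeps the MIX
   series rising-then-flat rather than overshooting.
3. *Stage-2 balance.* Equal fractional drift rates preserve r_sc·c_sc to
   first order, making MIX flat in stage 2 at the baseline temperature
   while conductance keeps rising and the 1 kHz magnitude keeps falling —
   the observed steady-state MIX plateau after ~60 min.

**Temperature presets.** Stage-2 drift multipliers relative to 22 °C:
conductance {1, 1, 1, 1, 2.5, 5} and resistance {1, 1, 1.6, 2.2, 2.8, 6}
at {12, 22, 32, 42, 52, 72} °C, linearly interpolated in between, range
error outside 0–100 °C. The capacitance-drift multiplier is derived from
the conductance target via the high-frequency scaling |Z_sc| ∝
r_sc^(1−p)·c_sc^(−p). A two-element circuit cannot satisfy all three
reported patterns (flat conductance 12–42 °C, linearly growing resistance
decline above 22 °C, *and* MIX-neutral drift below 72 °C) at once — MIX
neutrality algebraically ties the conductance rate to the resistance rate —
so the presets prioritise the conductance and resistance patterns and
guarantee MIX neutrality at the baseline and a distinct MIX decline at
72 °C; at intermediate temperatures the simulated MIX drifts mildly
negative. This is a known, documented compromise of the generator.

**Instruments.** HP: single 300 kHz frequency, reported directly as a
conductance series. NE: 35 log-spaced frequencies, 1 kHz–2.5 MHz. 4E:
10^(1+k/4) Hz for k = 0..20 with the 60-scan schedule (20 s intervals for
scans 1–20, then 1, 2.5, 5 and 10 min blocks of ten — 3 h 11 min total).
The exact 12 time points of the 16 min protocol are not published; the
default grid (0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 10, 13, 16 min) is denser
early where the response changes fastest, and configurable.

**Noise.** Per (time, frequency) point: multiplicative Gaussian noise on
|Z| (CV 0.02) and additive Gaussian phase noise (SD 1°). Per replicate: a
truncated log-normal scale factor (CV 0.30, clipped to [0.45, 2.2])
multiplies the whole r_sc curve — initial and plateau jointly, a membrane
thickness/area effect. Scaling the whole curve (rather than the initial
value alone) keeps every replicate's trajectory well-formed and leaves the
scale-invariant conversion α untouched, which is exactly why the real 4E
data must be normalized but still supports kinetics fitting. One seeded
generator drives everything in a documented stream order (replicate factors
first, then per replicate/time one magnitude and one phase vector), so a
seed reproduces a dataset byte-identically.

**Rate recovery.** The simulator round-trip (generate → extract response →
α → −ln(1−α) regression) recovers k_stage1 only through a response that is
affine in r_sc: the 1 kHz, conductance and MIX responses are nonlinear
transforms of the two relaxing elements and show apparent rates tens of
percent away from k_stage1 even on noiseless data — the same reason the
published per-response rate constants differ for one hydration process.
The recovery route therefore reads the DC-limit resistance (mean |Z| over
the three lowest 4E frequencies, 10–31.6 Hz, where the CPE branch is open)
and takes the conversion's final measurement at the last scan before the
stage-2 break (3380 s) — using the 16 min mark instead leaves a visible
truncation bias at small k (≈ +3.6% at k = 0.004 s⁻¹) because EIR_f has
not reached the plateau. With these choices the noiseless bias is ≤ 0.7%
over k ∈ {0.004, 0.008, 0.014} s⁻¹, and the median over five default-noise
replicates typically lands within a few percent (the five regression
points of the 30–120 s window bound the attainable precision; occasional
seeds reach ~10–14% at the slowest rate).

## What the generator does and does not emulate

Emulated: the two-stage trajectory shape, response directions and rough
magnitudes (conductance ~100–500 µS, |Z(1 kHz)| ~100–280 kΩ), instrument
grids and schedules, measurement noise, replicate-scale biological
variation, and the qualitative temperature patterns of the second stage.
Not emulated: electrode–skin contact impedance (the known 1–10 kHz caveat
of lateral-electrode instruments), the cartilage-related disturbances that
made the in vitro NE data unusable, drift or autocorrelated noise,
response-specific kinetics beyond what the circuit induces, and any
mechanistic water-transport physics. Passing tests therefore demonstrate
that the analysis chain is correct and self-consistent under the stated
statistical assumptions — not that those assumptions describe real skin.

## Problem sizes and numerical conventions

Tests and the acceptance script run the simulator at the study's own
scales (5 replicates × 60 scans × 21 frequencies for 4E; 12 sweeps × 35
frequencies for NE), which completes in seconds. Tabulated-constant
computations are closed-form. Conventions collected in one place:
round-half-up for whole minutes; sample SD (n−1) for table summaries and
SEM for rate profiles (missing when n = 1); log-nearest frequency matching
with lower-frequency tie-break; free-intercept regressions; window
endpoints inclusive; R² exclusion threshold 0.75 (the validity bound for
the first-order model) with a 0.95 high-quality subgroup; decimal CSV
output at 10 significant digits.

## Limitations

The degree-of-hydration percentage is an interpretation (the cumulative
reading of a quantity whose literal definition is a derivative); the
published mapping is not stated. The 4E conductance frequency is the grid
point nearest 300 kHz (316.2 kHz) because the published 251 kHz does not
exist on a 4-frequencies-per-decade grid. Correlation analyses on mean
curves with ~10–12 points have low resolution, and all temperature
conclusions inherit the two-knob circuit compromise described above.
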