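# Methods

## The index

The Wet Bulb Globe Temperature combines three thermometer readings with
fixed ISO weights:

    WBGT = 0.7·T_w + 0.2·T_g + 0.1·T_a        (°C)

T_a is the 2 m (dry-bulb) air temperature, T_g the temperature of a
standard 0.15 m black globe (integrating radiation and convection), and
T_w the natural wet-bulb temperature of a freely ventilated wetted wick
(integrating evaporative cooling). Neither T_g nor T_w is available on
weather grids, so both are modelled from standard fields: air
temperature, dew point, wind speed and mean radiant temperature (T_MRT).

## Globe temperature from mean radiant temperature

Mean radiant temperature is the uniform surrounding-surface temperature
that would produce the same radiant exchange on a body as the real
environment. A globe in equilibrium balances radiant gain against
convective loss to the air, giving the forced-convection relation

    T_MRT⁴ = T_g⁴ + (h_cg / (ε·D^0.4))·(T_g − T_a)        [Kelvin]

with the wind-damped mean convection coefficient

    h_cg = 1.1×10⁸ · v_a^0.6

(v_a the 10 m wind speed in m/s; the sub-linear exponent deliberately
reduces the weight of high winds). Solving for T_g means finding the
root of f(T_g) = T_g⁴ + C·T_g − (T_MRT⁴ + C·T_a), C = h_cg/(ε·D^0.4).
f is a positive quartic plus a positive linear term, hence strictly
increasing: the physical root is unique and lies between T_a and T_MRT.

**Solver.** Safeguarded Newton from the bracket midpoint, clamped to
[min(T_a, T_MRT), max(T_a, T_MRT)], absolute tolerance 10⁻⁸ K, fully
vectorized with no coupling between cells — every cell converges in a
handful of quadratic steps, so the per-cell work is fixed and small
(the point of this route over iterative psychrometric schemes). Two
limits short-circuit exactly: v_a = 0 gives C = 0 and T_g = T_MRT (no
convective exchange), and T_MRT = T_a gives T_g = T_a. Tests verify the
solver against an independent bracketed bisection and by substituting
T_g back into the balance (round-trip to 10⁻⁶ K on 10⁴ random states).

**Parameters.** D = 0.15 m (standard globe). Emissivity ε defaults to
0.98 (clothed human body); 0.95 (the globe instrument) is selectable via
`ThermalConstants(emissivity=0.95)`. Both values are defensible; the
choice shifts C by ~3 % and solved T_g by far less, but it is logged on
every CLI run because it is a genuine point of divergence between WBGT
implementations. No minimum-wind floor is imposed: calm air legitimately
yields T_g = T_MRT (a configurable floor can be emulated by clipping the
wind field before the call).

## Wet-bulb temperature (Stull fit)

The natural wet-bulb temperature uses Stull's empirical fit

    T_w = T_a·atan(0.151977·√(RH + 8.313659)) + atan(T_a + RH)
          − atan(RH − 1.676331) + 0.00391838·RH^1.5·atan(0.023101·RH)
          − 4.686035

with T_a in °C and RH in percent, calibrated for T_a ∈ [−20, 50] °C and
RH ∈ [5, 99] %. It is closed-form — no per-cell iteration — and
reproduces its published check value T_w(20 °C, 50 %) ≈ 13.7 °C.

RH is derived from the dew point as 100·e_s(T_d)/e_s(T_a) using Buck's
over-water saturation vapour pressure

    e_s(t) = 6.1121 · exp(17.502·t / (240.97 + t))    [hPa, t in °C]

Water-phase only, by design: WBGT is a human heat index and ice-phase
saturation is irrelevant to its valid range. Supersaturated inputs
(T_d > T_a, common in interpolated grids) clamp RH to 100 %.

**Out-of-range handling.** Global grids always contain polar and arid
cells outside the fit's domain. Default (permissive) mode evaluates the
formula everywhere and returns a validity flag; strict mode returns NaN
outside the domain. In the full composition, RH is additionally clamped
to at most 99 % before the Stull evaluation (saturated cells sit on the
fit's calibration boundary), while the validity flag reflects the
unclamped inputs.

**Known artefacts of the fit**, confirmed by a dense grid scan and
guarded by tests: the fit can exceed the air temperature slightly
(≤ 0.5 °C for T_a ≥ 0 °C, up to ~2.4 °C at the −20 °C / 5 % corner),
and it is non-monotone in RH for T_a below ~5 °C at very low humidity.
Both artefacts live at cold/dry extremes where heat stress is not at
issue; they are documented rather than patched, since altering the fit
would break comparability with other implementations.

## ACSM87 comparator

The American College of Sports Medicine linear model

    WBGT_ACSM87 = 0.567·T_a + 0.393·e + 3.94    (T_a in °C, e in hPa)

is included as the historical comparator. `e` defaults to the *actual*
vapour pressure (saturation pressure at the dew point), so the index
responds to humidity; the literal reading (saturation pressure at T_a)
is selectable via `e_mode="saturation"`. The default is the
interpretation under which the model behaves as a humidity index at all;
with the literal reading it collapses to a function of temperature
alone.

## Grid pipeline and aggregation

All point formulas are applied cell-wise over (time, lat, lon) stacks;
tests assert exact equality with a scalar per-cell loop. Conventions:
input grids in Kelvin and m/s (ERA5 style, with °C inputs converted on
read and unknown units rejected), hourly UTC timestamps, latitude
ascending, longitude normalized to [−180, 180).

- **Daily maximum**: per UTC calendar day, cell-wise maximum over the
  available hours; missing hours are ignored unless the whole day is
  missing. A `tz_offset_hours` option shifts to local days for users who
  prefer physical-day fidelity; UTC is the default for reproducibility.
- **Monthly mean of daily maxima**: arithmetic mean over the daily
  fields present — the canonical heat-stress map quantity.
- **Land-sea masking**: cells with land fraction below 0.5 (default)
  become missing; binary masks pass through unchanged.

Output files are NetCDF3 classic (xarray scipy backend) with °C units,
the method label and all resolved constants recorded as attributes, and
NaN as the declared fill value.

## Categories and evaluation statistics

ISO-derived heat-stress categories with left-closed boundaries except at
the top: <23 → 0, [23, 25) → 1, [25, 28) → 2, [28, 30) → 3,
[30, 33] → 4, >33 → 5. The asymmetry at the top is deliberate: 33 °C is
the critical health threshold, and only values strictly above it fall in
the "resting only" category 5.

Comparison statistics between a candidate and a reference WBGT set:
MAE over all finite pairs; MAE over the heat-stress subset (reference
strictly above 23 °C — the subset is defined on the reference, so it is
not symmetric); R² as the squared Pearson correlation; slope and
intercept by ordinary least squares of candidate on reference. Fewer
than two pairs or zero variance flag R²/slope/intercept as NaN while MAE
is still reported. Station-versus-grid comparison extracts the nearest
grid cell (no interpolation), inner-joins timestamps, takes daily maxima
of both series and runs the same statistics with the station as
reference.

## Synthetic fixtures

The generator emulates the structure the method assumes, not real
climate: air temperature = base + sinusoidal diurnal cycle (phase tied
to longitude via a fixed hour-angle function, no solar-geometry
dependency) + smooth latitudinal gradient + independent Gaussian noise;
dew point = air temperature minus a positive depression; T_MRT = air
temperature plus a daytime radiant excess (zero at night); wind
truncated-Gaussian at zero. Defaults describe a warm-humid month
(base 300 K, 6 K diurnal half-range, 5 K mean dew-point depression,
3 m/s mean wind, 15 K peak radiant excess) on an 8×8, 31-day hourly
grid, which keeps ≥95 % of cells inside the Stull domain; a polar
configuration (base 250 K) deliberately violates it to exercise
flagging.

What passing tests therefore show: the formulas, solver, aggregation and
statistics are internally correct and self-consistent on data with the
right gross structure. What they do not show: skill against real
reanalysis or observations — the fixtures have no spatial noise
correlation, no weather systems, no clouds, and no real radiative
transfer, and the published global comparisons require external
reanalysis and observation datasets.

## Problem sizes

The test suite runs the globe-solver verification on 10⁴ random states,
the Stull equivalence scan on a 100×95 domain grid, and the end-to-end
pipeline check on an 8×8 grid over one 31-day hourly month (≈ 47 600
cell-hours) with a full per-cell scalar recomputation as oracle; these
sizes exercise every code path densely while keeping the default suite
fast.
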