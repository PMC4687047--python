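# Methods

This note records the models, parameter choices and numerical decisions
behind `soartrack`, and what the simulator-based tests do and do not
demonstrate about real tracking data.

## Geometry and track preparation

All planar geometry uses an equirectangular projection about a local
origin (the colony) with R = 6 371 000 m.  For a central-place forager
whose trips stay within a few tens of km this differs from great-circle
distances by < 0.1 % for steps under 5 km below 60° latitude (property-
tested against the haversine formula); full geodesics would add a
dependency without measurable benefit.  Timestamps are timezone-naive
UTC throughout, matching the usual tracking-CSV convention.

QC removes fixes seen by fewer than 4 satellites or with DOP strictly
greater than 3 (both configurable).  Fixes lacking quality fields pass:
absence means the file dialect omitted them, not that the fix is poor.
Height above ground is GPS altitude minus the nearest-cell DEM
elevation; at the grid resolutions in scope, bilinear interpolation
would change AGL by far less than GPS vertical error, so nearest-cell is
used.  "Negative altitude" screening defaults to negative *AGL* (the
derived quantity the rule protects); a raw GPS-altitude variant is
available behind `negative_rule="raw"`.  Half-hour rounding of
radiation-join times sends exact midpoints (:15, :45) up; duplicate
timestamps keep the first fix and log a warning.

## Trip segmentation

A candidate trip is a maximal excursion outside the 300-m colony
presence radius, bounded by the last fix inside before departure and the
first fix back inside.  Re-entries shorter than twice the sampling
interval do not split an excursion (a single missed or wandering fix is
noise, not a trip boundary).  Excursions that touch the track ends
(unrecorded departure/arrival) are incomplete and dropped; excursions
overlapping 21:00–04:00 UTC are treated as roosting away and dropped by
default.

The foraging event is found by scoring trailing windows (60 s at 1 Hz,
at least 3 fixes at coarser intervals) on three criteria: radius of
gyration ≤ 150 m ("clumped"), median AGL ≤ 30 m ("low"), speed
coefficient of variation ≥ 0.6 ("highly variable").  The speed criterion
is waived when a window holds fewer than 4 fixes, where a CV is
meaningless.  Non-qualifying gaps shorter than one window are closed
before taking the longest qualifying run: the window is the smoothing
scale, and isolated window failures must not split a long bout.  These
thresholds are this package's calibration on the simulator — field
studies defer them to protocol papers — and every threshold used is
echoed into the output tables' metadata headers.  Trips whose event
touches a boundary are dropped so both commutes are non-empty, which
downstream commute metrics require.

## Thermal-soaring detection

Detection runs only on ~1-Hz segments (coarser data cannot resolve
circling and raise an explicit error).  Headings from consecutive fixes
are smoothed by a centred circular moving average (±2 s); the signed
heading difference gives a turn-rate series.  "Circular pattern" is
operationalised as same-sign turning at ≥ 10°/s accumulating ≥ 270°:
a small raptor circling at radius 15–40 m and 7–10 m/s turns 12–35°/s,
while heading noise on straight flight with ~3 m GPS error stays well
below 10°/s after smoothing.  Interruptions shorter than the merge gap
(5 s) are absorbed unless dominated by opposite-sign circling (flip
tolerance 2 s).  Candidates are truncated to their climbing phase by
trimming edges whose 3-s net climb is negative — the gliding tail of a
circling bout may hide flapping — and accepted when duration > 5 s and
net ascent ≥ 10 m.  Total ascent is the endpoint AGL difference, not the
sum of positive increments, which altitude noise would inflate; mean
climb speed is ascent/duration.  Direction is recorded as mixed when the
minority sign contributes > 20 % of cumulative turn.

A brute-force oracle in the test suite re-states the event definition
declaratively (enumerating all qualifying sub-ranges and keeping maximal
ones) and must agree exactly with the detector on noise-free tracks.

## Flight variables and aggregation

Cross-country speed is beeline displacement over duration (standard
soaring usage); a path-length variant is available via `path_speed`.
"Maximum" altitude is the third quartile of AGL with the linear-
interpolation (type-7) quantile convention, robust to single-fix
altitude outliers.  Solar radiation is joined at the commute start time
rounded to the nearest half-hour, falling back to the first trip fix
when no outward commute was recorded.  Six-hour aggregates pool all
individuals and flights per colony on the fixed 00/06/12/18 UTC grid
(half-open intervals), matching the native resolution of uplift
reanalysis products; sunrise-anchored intervals were rejected for
reproducibility.  Trip distance and duration are averaged on the natural
log scale by default (right-skewed distributions; geometric-style
means), with the arithmetic alternative behind `log_transform=False`.
Daily foraging time sums trip durations per (individual, date); a day
counts as complete when coverage spans sunrise to sunset (NOAA solar
geometry, civil zenith 90.833°) with no gap over 6× the sampling
interval.

## Energetics

Mechanical power is the classical three-component model: induced
k(mg)²/(2ρVS_d) with k = 1.2 and S_d = πb²/4; parasite ½ρV³S_b·C_Db with
S_b = 0.00813·m^0.666 and C_Db = 0.1; profile power a speed-independent
X₁ = 8.4/Ra multiple of the absolute minimum of the other two.  Chemical
power divides by muscle conversion efficiency η = 0.23 and multiplies by
respiration factor R = 1.1; maintenance power is the *measured* resting
metabolic rate (4.03 mL O₂/min × 20.1 kJ/L = 1.35 W) rather than an
allometric basal rate, and R is applied to it as well (switchable via
`respiration_on_maintenance`).  With these frozen defaults the curve
gives V_mp = 31.24 km/h, P_chem(V_mp) = 4.90 W, V_mr = 56.04 km/h,
P_chem(V_mr) = 6.28 W for the default morphology.  V_mp is located by
bounded scalar minimisation after a 0.1 m/s grid scan; V_mr maximises
V/P_chem, equivalent to the tangent from the origin, and the tangent
identity P′(V_mr) = P(V_mr)/V_mr is verified to 1 % in the tests.
Soaring-gliding flight is costed as κ_soar × resting rate with
κ_soar = 1.2 by default; flight theory quotes ~1.5 × basal metabolic
rate, but against the higher measured resting rate used here 1.2 is the
consistent multiplier, and κ_soar is exposed for either view.  Energy
ledger arithmetic: trip energy P·t, daily components P·hours·3.6 kJ, and
the minimum integer prey count p with p·E_prey ≥ n_trips·E_trip.

## Simulator

`simulate_day` emits 1-Hz days of colony rest, outward commute, foraging
bout and inward commute.  Flapping commutes fly straight at 7.4 m/s
(~26.5 km/h, the observed flapping cross-country speed) at ~20 m AGL.
Soaring commutes alternate helical climbs (radius 25 m at 8 m/s →
18.3°/s) and straight glides (9 m/s airspeed, glide ratio 7); climb rate
is (0.4 + 0.0016·R(t)) × U(0.7, 1.4) m/s clipped to 0.25–3.5 m/s, so
realised climbs stay inside the observed 0.26–3.56 m/s range and
strengthen with radiation.  Thermal availability per commute is
Bernoulli with p(R) = 0.5 + 0.45·logistic((R − 400)/140), rising from
~0.5 in weak radiation to ~0.95 near the clear-sky peak (950 Wh/m²
half-hourly half-sine).  Foraging bouts alternate hover (~0.45 m/s) and
dash (~7.5 m/s) inside a 100-m patch at 3–26 m AGL for 1800 s; soar-mode
patches are drawn ~2.7× farther (3.5 km vs 1.3 km lognormal means),
mirroring the observed spatial segregation of foraging areas.  Gaussian
noise (σ_xy = 3 m, σ_z = 4 m) and sporadic low-quality fixes
(p = 0.002, satellite count 3 or DOP 3.5) are applied *after* the
geometry, so recorded ground truth — radius-crossing trip boundaries,
bout ranges, per-thermal index span/ascent/climb — is exact.  Identical
seeds give byte-identical output.

What the simulator does not emulate: wind and thermal drift, slope
(orographic) soaring, behavioural decision-making (prey depletion,
competition), altitude-dependent thermal structure, or GPS error beyond
white noise and occasional flagged fixes.  Tests passing on this
generator therefore show that the detectors recover the *geometry* they
were designed for at realistic noise, not that field data are this
clean; on real tracks, drifting thermals and autocorrelated GPS error
will loosen boundary accuracy first.

## Problem sizes in the shipped checks

The test suite exercises detector recovery on 200 simulated thermalling
commutes, segmentation on 50 simulated 3-trip days, and the
radiation-trend property on 20 replicates of 480 commutes scheduled at
four radiation levels (~100/300/490/720 Wh/m², i.e. one commute batch
per 200-Wh/m² bin).  These sizes give the binomial comparisons enough
resolution for the stated thresholds while keeping the whole suite
around two minutes on one core.

## Known limitations

* The exact formula variant of the referenced flight-performance
  software is not recoverable from its published outputs; the frozen
  constants reproduce its printed speeds and powers to a few percent,
  not bit-exactly.
* Detector thresholds (turn rate, cumulative turn, smoothing, merge
  gaps) are simulator-calibrated defaults, not field-fitted values; they
  are reported in every output's metadata so downstream analyses can
  condition on them.
* Statistical modelling of the resulting tables (mixed models, smoothing
  splines, multiple-testing control) is deliberately out of scope: the
  pipeline emits the analysis-ready tables such models consume.
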