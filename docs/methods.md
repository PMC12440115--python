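# Methods

## Scope and data model

`hrrrsfc` converts hourly gridded surface forecasts (HRRR-style variables at
3-km cells) into AERMET-compatible `.sfc` surface files under three
derivation scenarios, and scores downstream dispersion predictions against
monitor observations. An hourly series is a pandas DataFrame indexed by UTC
timestamps with one column per variable; the registry in
`hrrrsfc.fields.HRRR_VARIABLES` maps each column to the GRIB2 variable
description it corresponds to, so fixture tables (CSV, either naming
convention in the header) and gridded sources share one key set. GRIB2
decoding itself is outside this package; any reader that yields the listed
variables per hour and cell can feed the pipeline.

All timestamps are handled internally in UTC. The `.sfc` convention is local
standard time, so the record builders take an integer UTC offset and apply
it when deriving the date fields; the hour label uses the hour-ending
convention (local clock hours 00–23 label records 1–24).

## Boundary-layer classification

Hours are classified convective (CBL) when the visible-beam downward solar
flux is strictly positive and stable (SBL) otherwise. The flux is a proxy
for the solar-angle test AERMET itself uses: it is identically zero at night
and positive in daylight. Values that are zero or negative (numerical noise)
are stable by the ≤ 0 rule.

## Surface-variable derivations (Scenario 1)

* **Convective velocity scale** w\* = (g H Z_ic / (ρ c_p T_ref))^{1/3}, with
  the boundary-layer height standing in for the convective mixing height and
  T_ref the 2-m temperature in kelvin. For H ≤ 0 the real cube root of the
  (negative) product is not meaningful; those hours emit the AERMET missing
  sentinel −9.
* **Monin–Obukhov length** L = ρ c_p T_ref u\*³ / (k g H). The expression is
  implemented exactly as stated, **without** a leading minus sign, so
  sign(L) = sign(H) and daytime convective hours have L > 0 — the inverse of
  the textbook Obukhov convention. This is deliberate and documented here
  prominently; consumers expecting the textbook sign must negate the column.
  Near-neutral hours (|H| < ε, default 10⁻⁶ W/m², configurable) emit +8888,
  which coincides with the bounded-scenario cap on |L| and avoids a division
  by approximately zero.
* **Wind direction** WD = mod(180 + (180/π) atan2(u, v), 360), yielding the
  meteorological "blowing-from" direction. Calm hours (u = v = 0, where
  atan2 is ill-defined) emit 0 and are counted in the log.
* **Albedo** is fixed at 1 during stable hours and (SW↓ − SW↑)/SW↓ during
  convective hours, clamped to [0, 1] because instrument-level noise can
  report SW↑ > SW↓. A convective hour with non-positive SW↓ (inconsistent
  with the classification) falls back to 1 with a warning.
* **Bowen ratio** |H / LE|. Hours with LE exactly 0 would be infinite; they
  receive the location's series median of |H/LE| over nonzero-LE hours,
  computed in a first pass and applied in a second. A series with no
  nonzero-LE hour at all falls back to 1.0 (logged) — the substitution rule
  presupposes at least one such hour.
* **Constants**: g = 9.8 m/s², ρ = 1.293 kg/m³ (dry air at 273 K and
  101.325 kPa), c_p = 1004 J/(kg·K), k = 0.4. All overridable through the
  plain-text configuration.
* **Pass-throughs and conversions**: u\*, z₀, wind speed, relative humidity
  and precipitation pass through; temperature gains 273.15; surface pressure
  (Pa) is divided by 10 — note this yields tens of pascals, not millibars;
  it is implemented exactly as specified for format compatibility and
  flagged here. Cloud cover becomes ⌊%/10⌋ after clamping to [0, 100]. The
  mechanical mixing height uses the equilibrium-level geopotential height as
  a proxy and is passed through without reinterpretation. The vertical
  potential temperature gradient has no gridded proxy and is fixed at −9;
  the precipitation-type code is fixed at 11 (liquid); the ASOS wind
  adjustment flag is "NAD" (no station winds are involved) and the
  substitution flag "NoSubs".

## Scenario 2 — physical bounds

Raw inputs are clamped first: H to [−64, 800] W/m², LE to [−100, 800] W/m²,
u\* and z₀ to [0, 2], Z_ic capped at 4000 m. w\*, L and the Bowen ratio are
recomputed from the clamped inputs, then clamped to [0, 2], [−8888, 8888]
and [−10, 10] respectively. The w\* sentinel (−9) of stable hours is
preserved through clamping, so the emitted w\* domain is [0, 2] ∪ {−9}.
Clamping is idempotent; when nothing (raw or derived) exceeds a bound the
Scenario-2 output is identical to Scenario 1 field-by-field.

## Scenario 3 — boundary-layer split

Convective hours replace the forecast sensible heat with the surface
energy-balance residual H = (SW↓ + LW↓ − SW↑ − LW↑) − G − LE and recompute
w\* and L from it, re-applying the Scenario-2 bounds; stable hours are
byte-identical to the Scenario-2 output. Two choices were genuinely open:

* the LE entering the energy balance is the Scenario-2-clamped value, since
  the split builds on the revised variables (G has no stated bound and
  passes through raw);
* the Bowen ratio and albedo are *not* recomputed — only H, w\* and L change
  in convective hours, so an all-night series collapses Scenario 3 onto
  Scenario 2 exactly.

## Ingest repairs

The analysis product (f00) carries all variables except precipitation, which
is identically zero there; the one-hour forecast (f01) supplies `precip_1h`.
`merge_precip` takes only that column from the forecast and errors, listing
the hours, if any analysis hour lacks a forecast match.

Missing hours are repaired by copying the nearest available earlier hour,
walking back at most `max_backtrack` hours (default 6 — the stated rule is
"use the prior hour, else the hour before that"; the cap generalises it
while preventing silent multi-day copying). Hours that cannot be filled are
flagged `unfillable`, excluded from `.sfc` output with a logged count. The
fill is idempotent and verified in the tests against an independent
linear-scan oracle.

Grid-cell selection minimises great-circle (haversine, spherical Earth
radius 6 371 008.8 m) or planar Euclidean distance, chosen by the grid's
declared coordinate system. For a 3-km grid the nearest-center distance is
bounded by the half-diagonal, 3000·√2/2 ≈ 2121.3 m.

## `.sfc` dialect

Whitespace-delimited, one header line (latitude/longitude with N/S–E/W
suffixes, station identifier strings, version tag) then one line per hour
with the 27 fields in canonical order. Written precisions: H, L, mixing
heights, temperatures, humidity and pressure 1 dp; u\*, w\*, z₀ 4 dp; Bowen,
albedo, wind speed and precipitation 2 dp; wind direction rounded to a whole
degree; date fields, precipitation code and cloud decile integers. AERMET
readers are free-format, so exact column widths are not part of the
contract; the reader here accepts arbitrary spacing, validates ranges (hour
1–24, cloud 0–10, direction [0, 360)) and reports the line number of any
malformed line. Round-trip identity holds to half a unit in the last written
decimal place.

## Evaluation statistics

Concentrations are converted from µg/m³ to ppb by the factor 0.53 (NO₂ at
25 °C and 1 atm: 24.465 L/mol over 46.006 g/mol). Hourly predictions are
averaged to daily values, retaining the contributing-hour count. Agreement
per site or stratum is scored by:

* OLS of measured on predicted values; R² equals the squared Pearson
  correlation (scipy's regression routine underneath);
* Willmott's (1981) original index of agreement
  d = 1 − Σ(Pᵢ−Oᵢ)²/Σ(|Pᵢ−Ō|+|Oᵢ−Ō|)², bounded [0, 1], equal to 1 iff the
  series coincide; two identical constant series (zero denominator) are
  defined as perfect agreement. The refined d₁ variant is intentionally not
  used.

Distance strata are half-open ([0,2), [2,10), [10,20), [20,35) km) with the
final bin closed on the left (≥35 km), so every distance maps to exactly one
bin. Stratum statistics pool site-days. Relative performance between two
meteorology sources is 100·(IOA_a − IOA_b)/IOA_a (positive ⇒ the first
source better). The site-level covariate regression is ordinary least
squares (statsmodels) of a site statistic on the supplied covariates, with
t-test p-values, a p < 0.05 significance flag and no multiple-testing
correction; exactly collinear or zero-variance covariates are rejected by
name before fitting.

## Synthetic data

The hourly generator emulates the structure the pipeline assumes at one
cell: a clipped-sinusoid diurnal visible-beam flux (exactly zero at night,
midday clear-sky peak 550 W/m² by default, weak seasonal modulation), with
short- and long-wave components, sensible/latent/ground fluxes tied to net
radiation (so daytime H is positive and nighttime H mildly negative), a
boundary layer growing with insolation (150 m nights to ~1500 m midday),
gamma-distributed winds around 3.5 m/s with u\* tied to speed, diurnal
temperature around 12 °C, anticorrelated humidity, near-standard pressure
and occasional precipitation. Defaults were chosen once as a realistic mild
mid-latitude year. Hours with exactly zero latent heat occur at rate 0.02
(exercising the Bowen median fallback); out-of-bound extremes in the five
bounded inputs can be injected at a configured rate (values drawn strictly
outside the bounds, locations recorded in `DataFrame.attrs["injected"]`);
listed hours can be removed to exercise gap repair. One seed governs
everything through spawned child streams, so a cell's series is invariant to
grid growth. The generator does **not** emulate spatial covariance between
cells, map projections, fronts/synoptic weather, or forecast error
structure — passing tests therefore demonstrate correctness of the
derivations and plumbing, not skill against real gridded forecasts.

The paired-series generator produces daily observation/prediction panels
with a target Pearson correlation (agreement 1 ⇒ identical series), site
means in 4–12 ppb, sites cycling through the five distance strata, and
synthetic site covariates (land-use shares from a Dirichlet draw, location,
elevation statistics, traffic volume).

## Numerical and design notes

* c_p appears in some sources as "1004 J/g/K"; the value is implemented as
  J/(kg·K), the only reading dimensionally consistent with ρ in kg/m³ and
  w\* in m/s.
* π in the wind-direction formula is `math.pi`; using 3.14 would shift
  directions by at most ~0.03°.
* The near-neutral threshold ε on |H| defaults to 10⁻⁶ W/m²; it only guards
  the exact-zero division, it is not a stability filter.
* Problem sizes in the test suite and acceptance script (10-day unit
  fixtures, 1008-hour formula recovery, 10 008-hour fuzzing, one 8760-hour
  round-trip year, 200 evaluation sites, 10 000 geometry sites) were chosen
  to exercise full-year code paths while keeping the whole suite in seconds.
* The geometry check samples 9000 sites uniformly plus 1000 in 3-m disks
  around randomly chosen four-center midpoints: the supremum region of the
  nearest-center distance has negligible area, so purely uniform sampling
  would verify the bound but almost never approach it.

## Known limitations

* No GRIB2 decoding and no Lambert-conformal projection handling; gridded
  sources must be extracted to the registry's variable set first, and
  lat/lon grids use spherical great-circle distance.
* The sign convention of L and the pressure/10 unit are reproduced as
  specified for compatibility, even where they depart from textbook
  conventions; both are flagged above.
* Upper-air (`.pfl`) profiles, AERMET input decks, precipitation-type
  inference and the vertical temperature gradient are out of scope.
* Scoring against real monitor networks requires externally prepared
  prediction/observation pairs; the bundled generator only emulates their
  statistical shape.
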