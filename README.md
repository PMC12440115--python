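# hrrrsfc

Surface meteorology for Gaussian dispersion models (AERMOD, R-LINE) is
normally preprocessed by AERMET from weather-station observations, which
leaves large areas far from any station poorly represented. `hrrrsfc`
generates AERMET-compatible hourly surface files (`.sfc`) from hourly 3-km
gridded forecast fields instead (HRRR-style variables: surface fluxes,
friction velocity, boundary-layer height, 2-m temperature and humidity, 10-m
winds, radiation components, pressure, cloud cover, one-hour precipitation),
and provides the statistics used to judge the resulting dispersion
predictions against monitor data.

It is aimed at air-quality and exposure modellers who want forecast-driven
meteorology as a drop-in replacement for observation-based `.sfc` files.

## What it computes

Each hour is classified convective (CBL, daytime) or stable (SBL, nighttime)
by the visible-beam downward solar flux (positive ⇒ CBL). Three derivation
scenarios are provided:

1. **Direct** — every surface variable derived straight from the gridded
   fields. The two stability scales are

   *convective velocity scale*  w\* = (g·H·Z_ic / (ρ·c_p·T_ref))^(1/3)
   (emitted only for H > 0; stable hours carry the −9 missing sentinel), and

   *Monin–Obukhov length*  L = ρ·c_p·T_ref·u\*³ / (k·g·H)
   with g = 9.8 m/s², ρ = 1.293 kg/m³, c_p = 1004 J/(kg·K), k = 0.4.
   Note the L expression carries **no leading minus sign**, so L > 0 under
   daytime convection — the inverse of the textbook sign convention; it is
   written to the `.sfc` file exactly as computed.

   Wind direction is WD = mod(180 + (180/π)·atan2(u, v), 360); daytime albedo
   is (SW↓ − SW↑)/SW↓ (1 at night); the Bowen ratio is |H / LE| with the
   series median substituted on zero-latent-heat hours; cloud cover becomes
   the AERMET decile ⌊%/10⌋; temperature is converted to kelvin and surface
   pressure divided by 10.

2. **Bounded** — the raw inputs are clamped to physically plausible ranges
   (H ∈ [−64, 800] W/m², LE ∈ [−100, 800] W/m², u\* and z₀ ∈ [0, 2],
   Z_ic ≤ 4000 m), w\*/L/Bowen are recomputed from the clamped values and
   then clamped themselves (w\* ∈ [0, 2], L ∈ [−8888, 8888], Bo ∈ [−10, 10]).

3. **Boundary-layer split** — CBL hours replace the forecast H with the
   surface energy-balance residual
   H = (SW↓ + LW↓ − SW↑ − LW↑) − G − LE,
   recompute w\* and L from it and re-apply the bounds; SBL hours keep their
   Scenario-2 values unchanged.

The evaluation module scores daily predictions against observations with an
ordinary least-squares fit of measured on predicted values (slope, intercept,
R²) and Willmott's index of agreement
d = 1 − Σ(Pᵢ−Oᵢ)² / Σ(|Pᵢ−Ō|+|Oᵢ−Ō|)², supports the five site-to-station
distance strata (<2, 2–10, 10–20, 20–35, ≥35 km), the relative IOA
difference 100·(IOA_a − IOA_b)/IOA_a, and a site-level OLS of performance on
land-use/terrain/traffic covariates. A seeded synthetic-data module supplies
physically structured hourly series and paired daily series so the whole
pipeline is testable without downloads.

## Worked example

```python
from hrrrsfc import (SynthConfig, generate_hourly_series, build_scenario3,
                     write_sfc, SfcHeader, generate_paired_series,
                     evaluate_pairs, convective_velocity_scale,
                     monin_obukhov_length)

hourly = generate_hourly_series(SynthConfig(seed=0, n_days=2))[(0, 0)]
records = build_scenario3(hourly, tz_offset=-7)          # local standard time UTC-7
write_sfc(SfcHeader(39.742, -104.991), records, "example.sfc")

print(convective_velocity_scale(100.0, 1000.0, 293.15))  # 1.37067548864422
print(monin_obukhov_length(100.0, 0.3, 293.15))          # 26.211980328061216

pairs = generate_paired_series(seed=0, n_sites=25, n_days=40, agreement=0.9)
print(evaluate_pairs(pairs["predicted"].to_numpy(), pairs["observed"].to_numpy()))
# EvalSummary(n=1000, slope=0.921..., intercept=0.614..., r_squared=0.882..., ioa=0.968...)
```

`example.sfc` starts with the station header and one line per hour in the
27-field order (date/hour, H, u\*, w\*, temperature-gradient sentinel, mixing
heights, L, z₀, Bowen, albedo, wind, temperature, precipitation, humidity,
pressure, cloud, flags):

```
  39.742N   104.991W  UA_ID: 00000  SF_ID: 00000  OS_ID: 00000  VERSION: 19191
...
19  1  1   1  6    274.2  0.1609   2.0000   -9.0   1535.7   4183.0      1.4  0.1500  0.79  0.80 ...
```

Here hour 6 of Julian day 1 is convective: the energy-balance H is
274.2 W/m², the recomputed w\* hit its 2 m/s cap, L is small and positive
(strong convection, inverted-sign convention), the temperature-gradient
column is the −9 sentinel, and every line ends `NAD NoSubs`.

The same pipeline is scriptable from the shell:

```sh
hrrrsfc simulate --seed 4 --days 3 --out fixtures/
hrrrsfc convert --source fixtures/cell_r0c0.csv --scenario 3 \
    --site-lat 39.7 --site-lon -105.0 --tz-offset -7 --out cell.sfc
hrrrsfc evaluate --pairs pairs.csv --by distance
```

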