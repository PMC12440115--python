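"""Derivation of AERMET surface variables from hourly gridded fields.

Three builders share one record assembly:

* Scenario 1 — direct derivation: fluxes, friction velocity, roughness and
  mixing heights pass straight through; the convective velocity scale w*, the
  Monin-Obukhov length L, the Bowen ratio, albedo, wind direction and the
  unit conversions are derived per the formulas below.
* Scenario 2 — physically bounded: the raw inputs (H, latent heat, u*, z0,
  Z_ic) are clamped to plausible ranges first, w*/L/Bowen are recomputed from
  the clamped values, and are then clamped themselves.
* Scenario 3 — boundary-layer split: daytime (convective, CBL) hours, flagged
  by a positive visible-beam downward solar flux, replace H with the surface
  energy-balance residual (net radiation minus ground and latent heat) and
  recompute w* and L from it, re-applying the Scenario-2 bounds; nighttime
  (stable, SBL) hours retain their Scenario-2 values unchanged.

Formulas (constants in :class:`~hrrrsfc.constants.PhysicalConstants`):

    w* = (g H Z_ic / (rho c_p T_ref))^(1/3)        for H > 0, else missing
    L  = rho c_p T_ref u*^3 / (k g H)              (+8888 when |H| ~ 0)
    WD = mod(180 + (180/pi) atan2(u, v), 360)

Note the L expression carries no leading minus sign, so L > 0 under daytime
convection — the opposite of the textbook Obukhov sign convention. It is
implemented this way deliberately; downstream consumers expecting the
textbook sign must negate it.
"""
from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_BOUNDS,
    DEFAULT_CONSTANTS,
    DEFAULT_H_EPS,
    MISSING,
    NEUTRAL_OBUKHOV,
    PhysicalConstants,
    ScenarioBounds,
)
from .fields import FLAG_UNFILLABLE, HRRR_VARIABLES

logger = logging.getLogger(__name__)

#: Serialized column order of one surface record (one .sfc line).
SURFACE_COLUMNS: list[str] = [
    "year", "month", "day", "julian_day", "hour",
    "sensible_heat", "friction_velocity", "w_star", "vptg_500m",
    "z_ic", "z_im", "obukhov_length", "surface_roughness",
    "bowen_ratio", "albedo", "wind_speed", "wind_direction", "wind_height",
    "temperature", "temperature_height", "precip_code", "precip_amount",
    "relative_humidity", "station_pressure", "cloud_cover",
    "adj_flag", "sub_flag",
]

CBL = "CBL"
SBL = "SBL"


def _as_array(*xs):
    arrs = [np.asarray(x, dtype=float) for x in xs]
    scalar = all(a.ndim == 0 for a in arrs)
    return arrs, scalar


def _ret(a: np.ndarray, scalar: bool):
    return float(a) if scalar else a


def classify_boundary_layer(visible_beam_downward_flux):
    """Classify hours as convective (``"CBL"``) or stable (``"SBL"``).

    A positive visible-beam downward solar flux marks daytime/convective
    conditions; zero (or any non-positive value) marks nighttime/stable.
    """
    (flux,), scalar = _as_array(visible_beam_downward_flux)
    if not np.all(np.isfinite(flux)):
        raise ValueError("visible-beam flux must be finite")
    regime = np.where(flux > 0, CBL, SBL)
    return str(regime) if scalar else regime


def convective_velocity_scale(
    sensible_heat,
    z_ic,
    t_ref,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Convective velocity scale w* in m/s.

    ``w* = (g H Z_ic / (rho c_p T_ref))^(1/3)`` for positive sensible heat;
    non-convective hours (H <= 0), for which the real cube root is undefined
    or meaningless, return the -9 missing sentinel.
    """
    (H, zic, tref), scalar = _as_array(sensible_heat, z_ic, t_ref)
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(zic)) and np.all(np.isfinite(tref))):
        raise ValueError("w* inputs must be finite")
    if np.any(zic < 0):
        raise ValueError("convective mixing height must be non-negative")
    if np.any(tref <= 0):
        raise ValueError("reference temperature must be positive (Kelvin)")
    w = np.cbrt(constants.g * H * zic / (constants.rho_air * constants.cp_air * tref))
    out = np.where(H > 0, w, MISSING)
    return _ret(out, scalar)


def monin_obukhov_length(
    sensible_heat,
    friction_velocity,
    t_ref,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    h_eps: float = DEFAULT_H_EPS,
):
    """Monin-Obukhov length L in m, as ``rho c_p T_ref u*^3 / (k g H)``.

    Near-neutral hours (|H| < ``h_eps``) return the +8888 sentinel instead of
    dividing by ~zero. The expression carries no minus sign, so
    sign(L) = sign(H): positive under daytime convection.
    """
    (H, ustar, tref), scalar = _as_array(sensible_heat, friction_velocity, t_ref)
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(ustar)) and np.all(np.isfinite(tref))):
        raise ValueError("L inputs must be finite")
    if np.any(ustar < 0):
        raise ValueError("friction velocity must be non-negative")
    if np.any(tref <= 0):
        raise ValueError("reference temperature must be positive (Kelvin)")
    neutral = np.abs(H) < h_eps
    H_safe = np.where(neutral, 1.0, H)
    L = (
        constants.rho_air * constants.cp_air * tref * ustar**3
        / (constants.von_karman * constants.g * H_safe)
    )
    out = np.where(neutral, NEUTRAL_OBUKHOV, L)
    return _ret(out, scalar)


def wind_direction(wind_u, wind_v, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Meteorological wind direction in degrees [0, 360).

    ``WD = mod(180 + (180/pi) atan2(u, v), 360)`` — e.g. a pure southerly
    (v = 1) gives 180, a pure westerly (u = 1) gives 270. Calm hours
    (u = v = 0) return 0 and are counted in the log.
    """
    (u, v), scalar = _as_array(wind_u, wind_v)
    wd = np.mod(180.0 + (180.0 / constants.pi) * np.arctan2(u, v), 360.0)
    calm = (u == 0) & (v == 0)
    out = np.where(calm, 0.0, wd)
    n_calm = int(np.sum(calm))
    if n_calm:
        logger.info("%d calm hour(s) (u = v = 0): wind direction set to 0", n_calm)
    return _ret(out, scalar)


def albedo(downward_shortwave, upward_shortwave, regime):
    """Surface albedo: 1 at night (SBL); (down - up)/down by day, clamped to [0, 1].

    Daytime hours reporting non-positive incoming shortwave (inconsistent
    with the convective classification) fall back to 1 with a warning.
    """
    (down, up), scalar = _as_array(downward_shortwave, upward_shortwave)
    if not (np.all(np.isfinite(down)) and np.all(np.isfinite(up))):
        raise ValueError("shortwave fluxes must be finite")
    reg = np.asarray(regime)
    cbl = reg == CBL
    down_safe = np.where(down > 0, down, 1.0)
    ratio = np.clip((down - up) / down_safe, 0.0, 1.0)
    out = np.where(cbl & (down > 0), ratio, 1.0)
    bad = cbl & (down <= 0)
    if np.any(bad):
        logger.warning(
            "%d convective hour(s) with non-positive incoming shortwave; albedo set to 1",
            int(np.sum(bad)),
        )
    return _ret(out, scalar)


def bowen_ratio(sensible_heat, latent_heat, location_median):
    """Bowen ratio |H / latent|; zero-latent hours use the location median.

    The median is precomputed over the series (median of |H/latent| across
    hours with nonzero latent heat at the cell) and substituted wherever the
    latent heat flux is exactly zero.
    """
    (H, latent), scalar = _as_array(sensible_heat, latent_heat)
    latent_safe = np.where(latent == 0, 1.0, latent)
    out = np.where(latent == 0, location_median, np.abs(H / latent_safe))
    return _ret(out, scalar)


def cloud_cover_decile(percent):
    """Cloud cover as an AERMET decile 0-10: floor(percent / 10).

    Out-of-range inputs are clamped to [0, 100] with a warning.
    """
    (p,), scalar = _as_array(percent)
    if np.any((p < 0) | (p > 100)):
        logger.warning(
            "%d cloud-cover value(s) outside [0, 100]; clamped",
            int(np.sum((p < 0) | (p > 100))),
        )
        p = np.clip(p, 0.0, 100.0)
    out = np.floor(p / 10.0).astype(int)
    return int(out) if scalar else out


def sensible_heat_cbl(
    downward_shortwave,
    upward_shortwave,
    downward_longwave,
    upward_longwave,
    ground_heat,
    latent_heat,
):
    """Energy-balance sensible heat: net radiation minus ground and latent fluxes.

    Net radiation = (down SW + down LW) - (up SW + up LW); the residual after
    removing the ground and latent heat fluxes is the convective-hour H.
    """
    (dsw, usw, dlw, ulw, g, le), scalar = _as_array(
        downward_shortwave, upward_shortwave, downward_longwave,
        upward_longwave, ground_heat, latent_heat,
    )
    out = (dsw + dlw - usw - ulw) - g - le
    return _ret(out, scalar)


# ---------------------------------------------------------------------------
# record assembly

def _require_fields(hourly: pd.DataFrame, cols: Iterable[str]) -> None:
    for col in cols:
        if col not in hourly.columns:
            raise KeyError(
                f"hourly series is missing {col!r} "
                f"(HRRR variable: {HRRR_VARIABLES.get(col, 'n/a')!r})"
            )


def _prepare(hourly: pd.DataFrame) -> pd.DataFrame:
    """Drop unfillable placeholder hours (logged) and validate presence."""
    _require_fields(hourly, HRRR_VARIABLES)
    if "fill_flag" in hourly.columns:
        bad = hourly["fill_flag"] == FLAG_UNFILLABLE
        if bad.any():
            logger.info("excluding %d unfillable hour(s) from output", int(bad.sum()))
            hourly = hourly.loc[~bad]
    return hourly


def _series_bowen_median(H, latent) -> float:
    nz = latent != 0
    if not np.any(nz):
        logger.warning("no nonzero-latent-heat hours; Bowen-ratio fallback median = 1.0")
        return 1.0
    return float(np.median(np.abs(H[nz] / latent[nz])))


def _assemble(
    hourly: pd.DataFrame,
    *,
    H: np.ndarray,
    u_star: np.ndarray,
    z0: np.ndarray,
    z_ic: np.ndarray,
    w_star: np.ndarray,
    obukhov: np.ndarray,
    bowen: np.ndarray,
    tz_offset: int,
) -> pd.DataFrame:
    local = hourly.index + pd.Timedelta(hours=tz_offset)
    regime = classify_boundary_layer(hourly["visible_beam_downward_flux"].to_numpy())
    rec = pd.DataFrame(index=hourly.index)
    rec["year"] = (local.year % 100).astype(int)
    rec["month"] = local.month.astype(int)
    rec["day"] = local.day.astype(int)
    rec["julian_day"] = local.dayofyear.astype(int)
    # hour-ending convention: local clock hours 00-23 label records 1-24
    rec["hour"] = (local.hour + 1).astype(int)
    rec["sensible_heat"] = H
    rec["friction_velocity"] = u_star
    rec["w_star"] = w_star
    rec["vptg_500m"] = MISSING
    rec["z_ic"] = z_ic
    rec["z_im"] = hourly["equilibrium_geopotential_height"].to_numpy(dtype=float)
    rec["obukhov_length"] = obukhov
    rec["surface_roughness"] = z0
    rec["bowen_ratio"] = bowen
    rec["albedo"] = albedo(
        hourly["downward_shortwave"].to_numpy(),
        hourly["upward_shortwave"].to_numpy(),
        regime,
    )
    rec["wind_speed"] = hourly["wind_speed_10m"].to_numpy(dtype=float)
    rec["wind_direction"] = wind_direction(
        hourly["wind_u_10m"].to_numpy(), hourly["wind_v_10m"].to_numpy()
    )
    rec["wind_height"] = 10.0
    rec["temperature"] = hourly["temperature_2m"].to_numpy(dtype=float) + 273.15
    rec["temperature_height"] = 2.0
    rec["precip_code"] = 11
    rec["precip_amount"] = hourly["precip_1h"].to_numpy(dtype=float)
    rec["relative_humidity"] = hourly["relative_humidity_2m"].to_numpy(dtype=float)
    rec["station_pressure"] = hourly["surface_pressure"].to_numpy(dtype=float) / 10.0
    rec["cloud_cover"] = cloud_cover_decile(hourly["total_cloud_cover"].to_numpy())
    rec["adj_flag"] = "NAD"
    rec["sub_flag"] = "NoSubs"
    rec["regime"] = regime
    return rec


def build_scenario1(
    hourly: pd.DataFrame,
    tz_offset: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    h_eps: float = DEFAULT_H_EPS,
    bowen_median: float | None = None,
) -> pd.DataFrame:
    """Direct derivation of one surface record per hour (Scenario 1).

    ``tz_offset`` is the integer UTC offset of local standard time; the date
    and hour fields come from the shifted timestamp. ``bowen_median``
    overrides the series-computed zero-latent fallback (e.g. when processing
    a subset of a longer series).
    """
    hourly = _prepare(hourly)
    H = hourly["sensible_heat"].to_numpy(dtype=float)
    u_star = hourly["friction_velocity"].to_numpy(dtype=float)
    latent = hourly["latent_heat"].to_numpy(dtype=float)
    z_ic = hourly["pbl_height"].to_numpy(dtype=float)
    z0 = hourly["surface_roughness"].to_numpy(dtype=float)
    t_ref = hourly["temperature_2m"].to_numpy(dtype=float) + 273.15
    med = _series_bowen_median(H, latent) if bowen_median is None else bowen_median
    return _assemble(
        hourly,
        H=H,
        u_star=u_star,
        z0=z0,
        z_ic=z_ic,
        w_star=convective_velocity_scale(H, z_ic, t_ref, constants),
        obukhov=monin_obukhov_length(H, u_star, t_ref, constants, h_eps),
        bowen=bowen_ratio(H, latent, med),
        tz_offset=tz_offset,
    )


def apply_input_bounds(
    hourly: pd.DataFrame, bounds: ScenarioBounds = DEFAULT_BOUNDS
) -> pd.DataFrame:
    """Clamp the raw bounded inputs (H, latent, u*, z0, Z_ic) of a series.

    Values below a lower limit are set to that limit and values above an
    upper limit to that limit; the mixing height is capped only. All other
    columns pass through untouched. Idempotent.
    """
    out = hourly.copy()
    out["sensible_heat"] = np.clip(out["sensible_heat"], *bounds.sensible_heat)
    out["latent_heat"] = np.clip(out["latent_heat"], *bounds.latent_heat)
    out["friction_velocity"] = np.clip(out["friction_velocity"], *bounds.friction_velocity)
    out["surface_roughness"] = np.clip(out["surface_roughness"], *bounds.surface_roughness)
    out["pbl_height"] = np.minimum(out["pbl_height"], bounds.mixing_height_max)
    return out


def _clip_wstar(w: np.ndarray, bounds: ScenarioBounds) -> np.ndarray:
    # preserve the -9 missing sentinel of non-convective hours
    return np.where(w == MISSING, MISSING, np.clip(w, *bounds.w_star))


def apply_bounds_scenario2(
    hourly: pd.DataFrame,
    bounds: ScenarioBounds = DEFAULT_BOUNDS,
    tz_offset: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    h_eps: float = DEFAULT_H_EPS,
    bowen_median: float | None = None,
) -> pd.DataFrame:
    """Physically bounded derivation (Scenario 2).

    The raw inputs are clamped first; w*, L and the Bowen ratio are then
    recomputed from the clamped values and finally clamped to their own
    ranges (the w* missing sentinel of stable hours is preserved).
    """
    prepared = _prepare(hourly)
    hourly = apply_input_bounds(prepared, bounds)
    changed = (hourly[
        ["sensible_heat", "latent_heat", "friction_velocity", "surface_roughness", "pbl_height"]
    ] != prepared[
        ["sensible_heat", "latent_heat", "friction_velocity", "surface_roughness", "pbl_height"]
    ]).to_numpy().sum()
    if changed:
        logger.info("scenario 2: clamped %d out-of-bound input value(s)", int(changed))
    H = hourly["sensible_heat"].to_numpy(dtype=float)
    u_star = hourly["friction_velocity"].to_numpy(dtype=float)
    latent = hourly["latent_heat"].to_numpy(dtype=float)
    z_ic = hourly["pbl_height"].to_numpy(dtype=float)
    z0 = hourly["surface_roughness"].to_numpy(dtype=float)
    t_ref = hourly["temperature_2m"].to_numpy(dtype=float) + 273.15
    med = _series_bowen_median(H, latent) if bowen_median is None else bowen_median
    w = _clip_wstar(convective_velocity_scale(H, z_ic, t_ref, constants), bounds)
    L = np.clip(monin_obukhov_length(H, u_star, t_ref, constants, h_eps), *bounds.obukhov_length)
    bo = np.clip(bowen_ratio(H, latent, med), *bounds.bowen)
    return _assemble(
        hourly,
        H=H,
        u_star=u_star,
        z0=z0,
        z_ic=z_ic,
        w_star=w,
        obukhov=L,
        bowen=bo,
        tz_offset=tz_offset,
    )


def build_scenario3(
    hourly: pd.DataFrame,
    bounds: ScenarioBounds = DEFAULT_BOUNDS,
    tz_offset: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    h_eps: float = DEFAULT_H_EPS,
    bowen_median: float | None = None,
) -> pd.DataFrame:
    """Boundary-layer-split derivation (Scenario 3).

    Convective (daytime) hours replace the forecast sensible heat with the
    surface energy-balance residual, recompute w* and L from it, and re-apply
    the Scenario-2 bounds; stable (nighttime) hours are identical to the
    Scenario-2 output.
    """
    prepared = _prepare(hourly)
    rec = apply_bounds_scenario2(
        prepared, bounds, tz_offset, constants, h_eps, bowen_median
    )
    clamped = apply_input_bounds(prepared, bounds)
    cbl = (rec["regime"] == CBL).to_numpy()
    if not np.any(cbl):
        return rec

    H3 = sensible_heat_cbl(
        clamped["downward_shortwave"].to_numpy(dtype=float),
        clamped["upward_shortwave"].to_numpy(dtype=float),
        clamped["downward_longwave"].to_numpy(dtype=float),
        clamped["upward_longwave"].to_numpy(dtype=float),
        clamped["ground_heat"].to_numpy(dtype=float),
        clamped["latent_heat"].to_numpy(dtype=float),
    )
    H3 = np.clip(H3, *bounds.sensible_heat)
    u_star = clamped["friction_velocity"].to_numpy(dtype=float)
    z_ic = clamped["pbl_height"].to_numpy(dtype=float)
    t_ref = clamped["temperature_2m"].to_numpy(dtype=float) + 273.15
    w3 = _clip_wstar(convective_velocity_scale(H3, z_ic, t_ref, constants), bounds)
    L3 = np.clip(
        monin_obukhov_length(H3, u_star, t_ref, constants, h_eps),
        *bounds.obukhov_length,
    )
    out = rec.copy()
    out.loc[cbl, "sensible_heat"] = H3[cbl]
    out.loc[cbl, "w_star"] = w3[cbl]
    out.loc[cbl, "obukhov_length"] = L3[cbl]
    return out


def build_scenario(
    hourly: pd.DataFrame,
    scenario: int,
    bounds: ScenarioBounds = DEFAULT_BOUNDS,
    tz_offset: int = 0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    h_eps: float = DEFAULT_H_EPS,
) -> pd.DataFrame:
    """Dispatch to the scenario builder selected by number (1, 2 or 3)."""
    if scenario == 1:
        return build_scenario1(hourly, tz_offset, constants, h_eps)
    if scenario == 2:
        return apply_bounds_scenario2(hourly, bounds, tz_offset, constants, h_eps)
    if scenario == 3:
        return build_scenario3(hourly, bounds, tz_offset, constants, h_eps)
    raise ValueError(f"unknown scenario {scenario!r} (expected 1, 2 or 3)")
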