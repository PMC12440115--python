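"""Hourly-field schema and the HRRR variable registry.

An hourly series is carried as a :class:`pandas.DataFrame` indexed by UTC
timestamps, one row per hour, with one column per surface variable. The
registry below maps each internal column name to the HRRR GRIB2 variable
description it is extracted from, so that gridded sources and fixture tables
share one set of keys: a fixture CSV may use either the short column names or
the full description strings as headers.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Internal column name -> HRRR wrfsfc variable description.
HRRR_VARIABLES: dict[str, str] = {
    "sensible_heat": "SFC=Ground or water surface; Sensible heat net flux [W/(m^2)]",
    "friction_velocity": "SFC=Ground or water surface; Frictional velocity [m/s]",
    "pbl_height": "SFC=Ground or water surface; Planetary boundary layer height [m]",
    "equilibrium_geopotential_height": "EHLT=Equilibrium level; Geopotential height [gpm]",
    "surface_roughness": "SFC=Ground or water surface; Surface roughness [m]",
    "latent_heat": "SFC=Ground or water surface; Latent heat net flux [W/(m^2)]",
    "ground_heat": "SFC=Ground or water surface; Ground heat flux [W/(m^2)]",
    "temperature_2m": "2[m] HTGL=Specified height level above ground; Temperature [C]",
    "relative_humidity_2m": "2[m] HTGL=Specified height level above ground; Relative humidity [%]",
    "wind_u_10m": "10[m] HTGL=Specified height level above ground; u-component of wind [m/s]",
    "wind_v_10m": "10[m] HTGL=Specified height level above ground; v-component of wind [m/s]",
    "wind_speed_10m": "10[m] HTGL=Specified height level above ground; Wind speed [m/s]",
    "downward_shortwave": "SFC=Ground or water surface; Downward short-wave radiation flux [W/m^2]",
    "upward_shortwave": "SFC=Ground or water surface; Upward short-wave radiation flux [W/m^2]",
    "downward_longwave": "SFC=Ground or water surface; Downward long-wave radiation flux [W/m^2]",
    "upward_longwave": "SFC=Ground or water surface; Upward long-wave radiation flux [W/m^2]",
    "visible_beam_downward_flux": "SFC=Ground or water surface; Visible Beam Downward Solar Flux [W/m^2]",
    "surface_pressure": "SFC=Ground or water surface; Pressure [Pa]",
    "total_cloud_cover": "EATM=Entire Atmosphere; Total cloud cover [%]",
    "precip_1h": "SFC=Ground or water surface; 01 hr Total precipitation [kg/(m^2)]",
}

#: Columns every complete hourly series carries (registry keys + bookkeeping).
HOURLY_COLUMNS: list[str] = list(HRRR_VARIABLES) + ["fill_flag"]

#: Values of the per-hour provenance flag.
FLAG_OBSERVED = "observed"
FLAG_FILLED = "filled_prior_hour"
FLAG_UNFILLABLE = "unfillable"


def validate_hourly(df: pd.DataFrame, require_all: bool = True) -> None:
    """Check the hourly-series invariants, raising ``ValueError`` on breach.

    Checks: required columns present (each error names the HRRR source
    variable), relative humidity and cloud cover in [0, 100], non-negative
    wind speed, and strictly increasing hourly timestamps.
    """
    if require_all:
        for col, hrrr_name in HRRR_VARIABLES.items():
            if col not in df.columns:
                raise ValueError(
                    f"missing required field {col!r} (HRRR variable: {hrrr_name!r})"
                )
    if not isinstance(df.index, pd.DatetimeIndex):
        raise ValueError("hourly series must be indexed by timestamps")
    if len(df) > 1:
        deltas = df.index.to_series().diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            raise ValueError("timestamps must be strictly increasing")
    ok_rows = (
        df["fill_flag"] != FLAG_UNFILLABLE if "fill_flag" in df.columns
        else pd.Series(True, index=df.index)
    )
    for col, lo, hi in [
        ("relative_humidity_2m", 0.0, 100.0),
        ("total_cloud_cover", 0.0, 100.0),
    ]:
        if col in df.columns:
            vals = df.loc[ok_rows, col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"{col} outside [{lo}, {hi}]")
    if "wind_speed_10m" in df.columns:
        if (df.loc[ok_rows, "wind_speed_10m"].dropna() < 0).any():
            raise ValueError("wind_speed_10m must be non-negative")


def read_fixture_csv(path: str | Path) -> pd.DataFrame:
    """Read an hourly fixture table (one column per variable).

    The first column must be named ``timestamp`` (ISO date-hours, UTC).
    Remaining headers may be either the short registry names or the verbatim
    HRRR variable descriptions; the latter are renamed on read.
    """
    df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError(f"{path}: fixture table must have a 'timestamp' column")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.set_index("timestamp")
    reverse = {v: k for k, v in HRRR_VARIABLES.items()}
    return df.rename(columns=reverse)


def write_fixture_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an hourly series as a fixture table readable by :func:`read_fixture_csv`."""
    out = df.copy()
    out.index.name = "timestamp"
    out.to_csv(path)
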