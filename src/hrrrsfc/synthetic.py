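"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The hourly generator emulates what one year of 3-km hourly surface forecasts
looks like at a grid cell: a clipped-sinusoid diurnal solar cycle (so both
convective daytime and stable nighttime hours occur), sensible/latent/ground
heat fluxes tied to net radiation, a diurnally growing boundary layer,
plausible wind, temperature, humidity, pressure and cloud fields, occasional
hours with exactly zero latent heat (exercising the Bowen-ratio median
fallback), optional out-of-bound extremes at a configured rate (exercising
the bounded scenarios), and optional removed hours (exercising gap repair).
It makes no attempt to emulate spatial covariance between cells or a map
projection — cells differ only by seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import FLAG_OBSERVED, HRRR_VARIABLES

# fields eligible for out-of-bound injection and the ranges the injected
# values are drawn from (all strictly outside the scenario bounds)
_INJECTION_RANGES: dict[str, tuple[float, float]] = {
    "sensible_heat": (850.0, 1200.0),
    "latent_heat": (850.0, 1100.0),
    "friction_velocity": (2.1, 3.0),
    "pbl_height": (4200.0, 6000.0),
    "surface_roughness": (2.1, 3.0),
}


@dataclass
class SynthConfig:
    """Knobs of the hourly generator; defaults give a mild mid-latitude year.

    ``solar_peak`` is the clear-sky midday visible-beam flux (W/m^2);
    ``temp_mean``/``temp_amp`` the mean and diurnal half-range of the 2-m
    temperature (degC); ``outlier_rate`` the per-hour probability of one
    injected out-of-bound extreme; ``zero_latent_rate`` the per-hour
    probability of an exactly-zero latent heat flux; ``missing_hours`` a
    sequence of integer hour offsets removed from every cell's series.
    """

    seed: int = 0
    n_days: int = 30
    start: str = "2019-01-01"
    grid_rows: int = 1
    grid_cols: int = 1
    cell_spacing: float = 3000.0
    solar_peak: float = 550.0
    temp_mean: float = 12.0
    temp_amp: float = 6.0
    wind_mean: float = 3.5
    outlier_rate: float = 0.0
    zero_latent_rate: float = 0.02
    missing_hours: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("outlier_rate", "zero_latent_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _cell_series(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_days * 24
    idx = pd.date_range(cfg.start, periods=n, freq="h")
    h = idx.hour.to_numpy()
    doy = idx.dayofyear.to_numpy()

    season = 1.0 - 0.2 * np.cos(2 * np.pi * (doy - 172) / 365.0)
    elevation = np.sin(np.pi * (h - 6) / 12.0)
    elevation = np.where((h >= 6) & (h <= 18), np.clip(elevation, 0.0, None), 0.0)
    cloud = np.clip(rng.normal(45.0, 25.0, n), 0.0, 100.0)
    sky = 1.0 - 0.4 * cloud / 100.0
    visible = cfg.solar_peak * season * elevation * sky  # exactly 0 at night

    down_sw = visible / 0.75
    up_sw = np.clip(down_sw * (0.2 + rng.normal(0, 0.01, n)), 0.0, down_sw)
    temp = (
        cfg.temp_mean
        - cfg.temp_amp * np.cos(2 * np.pi * (h - 14) / 24.0)
        + 3.0 * (season - 1.0)
        + rng.normal(0, 0.8, n)
    )
    down_lw = 300.0 + 2.0 * temp + rng.normal(0, 8.0, n)
    up_lw = down_lw + 30.0 + rng.normal(0, 4.0, n)
    net_rad = down_sw + down_lw - up_sw - up_lw

    ground = 0.1 * net_rad + rng.normal(0, 2.0, n)
    latent = np.clip(0.45 * net_rad + rng.normal(0, 8.0, n), -40.0, 500.0)
    latent[rng.random(n) < cfg.zero_latent_rate] = 0.0
    sensible = np.clip(0.35 * net_rad - 5.0 + rng.normal(0, 5.0, n), -60.0, 700.0)

    wind_speed = np.clip(rng.gamma(4.0, cfg.wind_mean / 4.0, n), 0.5, 15.0)
    theta = rng.uniform(0, 2 * np.pi, n)
    wind_u = wind_speed * np.sin(theta)
    wind_v = wind_speed * np.cos(theta)
    u_star = np.clip(0.06 + 0.07 * wind_speed + rng.normal(0, 0.03, n), 0.05, 1.5)

    pbl = np.clip(150.0 + 2.3 * visible + rng.normal(0, 30.0, n), 50.0, 3500.0)
    z_im = np.clip(2000.0 + 4.0 * visible + rng.normal(0, 200.0, n), 500.0, 9000.0)
    rh = np.clip(70.0 - 2.0 * (temp - cfg.temp_mean) + rng.normal(0, 5.0, n), 20.0, 100.0)
    pressure = 101_325.0 + rng.normal(0, 300.0, n)
    precip = np.where(rng.random(n) < 0.05, rng.exponential(1.5, n), 0.0)

    df = pd.DataFrame(
        {
            "sensible_heat": sensible,
            "friction_velocity": u_star,
            "pbl_height": pbl,
            "equilibrium_geopotential_height": z_im,
            "surface_roughness": np.full(n, 0.15),
            "latent_heat": latent,
            "ground_heat": ground,
            "temperature_2m": temp,
            "relative_humidity_2m": rh,
            "wind_u_10m": wind_u,
            "wind_v_10m": wind_v,
            "wind_speed_10m": wind_speed,
            "downward_shortwave": down_sw,
            "upward_shortwave": up_sw,
            "downward_longwave": down_lw,
            "upward_longwave": up_lw,
            "visible_beam_downward_flux": visible,
            "surface_pressure": pressure,
            "total_cloud_cover": cloud,
            "precip_1h": precip,
            "fill_flag": FLAG_OBSERVED,
        },
        index=idx,
    )
    df.index.name = "timestamp"

    injected: list[tuple[pd.Timestamp, str]] = []
    if cfg.outlier_rate > 0:
        hit = np.flatnonzero(rng.random(n) < cfg.outlier_rate)
        fields = list(_INJECTION_RANGES)
        choices = rng.integers(0, len(fields), hit.size)
        for pos, which in zip(hit, choices):
            col = fields[which]
            lo, hi = _INJECTION_RANGES[col]
            df.iloc[pos, df.columns.get_loc(col)] = rng.uniform(lo, hi)
            injected.append((idx[pos], col))
    if cfg.missing_hours:
        keep = np.ones(n, dtype=bool)
        keep[list(cfg.missing_hours)] = False
        df = df.iloc[keep]
    df.attrs["injected"] = injected
    return df


def generate_hourly_series(cfg: SynthConfig) -> dict[tuple[int, int], pd.DataFrame]:
    """One hourly series per grid cell, keyed by (row, col).

    Deterministic for a fixed config: each cell's stream is spawned from the
    single config seed, so adding cells never changes existing ones. The
    injected out-of-bound values are recorded in each frame's
    ``attrs["injected"]`` as (timestamp, field) pairs.
    """
    out: dict[tuple[int, int], pd.DataFrame] = {}
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.grid_rows * cfg.grid_cols)
    k = 0
    for i in range(cfg.grid_rows):
        for j in range(cfg.grid_cols):
            out[(i, j)] = _cell_series(cfg, np.random.default_rng(children[k]))
            k += 1
    return out


_STRATUM_RANGES_KM = [(0.3, 1.9), (2.2, 9.5), (10.5, 19.5), (20.5, 34.5), (35.5, 60.0)]


def generate_paired_series(
    seed: int,
    n_sites: int = 25,
    n_days: int = 40,
    agreement: float = 0.8,
    bias: float = 0.0,
) -> pd.DataFrame:
    """Daily prediction/observation pairs with site metadata and covariates.

    ``agreement`` is the target Pearson correlation between predicted and
    observed daily values (1 gives exactly equal series, so downstream R^2
    and index of agreement are both 1). Sites cycle through the five
    station-distance strata, so each stratum is populated for n_sites >= 5.
    """
    if not 0 <= agreement <= 1:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2019-01-01", periods=n_days, freq="D")

    site_mean = rng.uniform(4.0, 12.0, n_sites)
    z_obs = rng.standard_normal((n_sites, n_days))
    eps = rng.standard_normal((n_sites, n_days))
    z_pred = agreement * z_obs + np.sqrt(1.0 - agreement**2) * eps
    observed = site_mean[:, None] + 3.0 * z_obs
    predicted = site_mean[:, None] + 3.0 * z_pred + bias

    lo = np.array([_STRATUM_RANGES_KM[i % 5][0] for i in range(n_sites)])
    hi = np.array([_STRATUM_RANGES_KM[i % 5][1] for i in range(n_sites)])
    distance = rng.uniform(lo, hi)
    land = rng.dirichlet([2.0, 3.0, 3.0, 2.0, 4.0], n_sites) * 100.0

    meta = pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(n_sites)],
            "site_lat": rng.uniform(25.0, 49.0, n_sites),
            "site_lon": rng.uniform(-124.0, -67.0, n_sites),
            "station_distance_km": distance,
            "median_aadt": 10 ** rng.uniform(3.0, 5.0, n_sites),
            "pct_high_density": land[:, 0],
            "pct_low_med_density": land[:, 1],
            "pct_forest": land[:, 2],
            "pct_agriculture": land[:, 3],
            "elevation_mean": rng.uniform(0.0, 2000.0, n_sites),
            "elevation_sd": rng.uniform(5.0, 300.0, n_sites),
            "mean_no2": site_mean,
        }
    )
    long = pd.DataFrame(
        {
            "site_id": np.repeat(meta["site_id"].to_numpy(), n_days),
            "date": np.tile(dates, n_sites),
            "predicted": predicted.ravel(),
            "observed": observed.ravel(),
        }
    )
    return long.merge(meta, on="site_id", how="left")
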