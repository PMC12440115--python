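import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hrrrsfc.synthetic import SynthConfig, generate_hourly_series

settings.register_profile("derandomized", derandomize=True, max_examples=50)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def hourly_series() -> pd.DataFrame:
    """Ten synthetic days at one cell, with zero-latent hours but no extremes."""
    cfg = SynthConfig(seed=7, n_days=10)
    return generate_hourly_series(cfg)[(0, 0)]


def make_inbounds_series(seed: int, n_days: int = 10) -> pd.DataFrame:
    """A series whose raw *and derived* quantities all sit inside the scenario bounds.

    The generator's fluxes are overwritten with controlled draws: daytime
    sensible heat in [50, 250] W/m^2 and nighttime in [-50, -10] (no
    near-neutral hours, so |L| stays far below its cap), friction velocity in
    [0.1, 0.8], mixing height capped at 1200 m (so w* stays below 2), and
    latent heat kept >= |H|/9 in magnitude (so the Bowen ratio stays below
    10). Used by the scenario-equivalence checks, whose premise is exactly
    this containment.
    """
    cfg = SynthConfig(seed=seed, n_days=n_days, solar_peak=350.0, zero_latent_rate=0.0)
    df = generate_hourly_series(cfg)[(0, 0)].copy()
    rng = np.random.default_rng(seed + 1)
    n = len(df)
    day = df["visible_beam_downward_flux"].to_numpy() > 0
    H = np.where(day, rng.uniform(50.0, 250.0, n), rng.uniform(-50.0, -10.0, n))
    df["sensible_heat"] = H
    df["friction_velocity"] = rng.uniform(0.1, 0.8, n)
    df["pbl_height"] = np.minimum(df["pbl_height"], 1200.0)
    latent = df["latent_heat"].to_numpy()
    floor = np.abs(H) / 9.0 + 1.0
    df["latent_heat"] = np.where(np.abs(latent) < floor, floor, latent)
    return df


@pytest.fixture()
def inbounds_series() -> pd.DataFrame:
    return make_inbounds_series(seed=11)
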