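"""Surface-variable derivations and the three scenario builders."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrrrsfc.constants import MISSING, NEUTRAL_OBUKHOV, ScenarioBounds
from hrrrsfc.scenarios import (
    albedo,
    apply_bounds_scenario2,
    apply_input_bounds,
    bowen_ratio,
    build_scenario1,
    build_scenario3,
    classify_boundary_layer,
    cloud_cover_decile,
    convective_velocity_scale,
    monin_obukhov_length,
    sensible_heat_cbl,
    wind_direction,
)
from hrrrsfc.synthetic import SynthConfig, generate_hourly_series

finite = st.floats(allow_nan=False, allow_infinity=False, width=32)


class TestScalarDerivations:
    @pytest.mark.parametrize(
        "flux, regime", [(0.0, "SBL"), (350.0, "CBL"), (-0.001, "SBL")]
    )
    def test_boundary_layer_classification(self, flux, regime):
        assert classify_boundary_layer(flux) == regime

    def test_wstar_reference_value(self):
        # (g H Zic / (rho cp Tref))^(1/3) evaluated by hand
        assert convective_velocity_scale(100.0, 1000.0, 293.15) == pytest.approx(
            1.3707, abs=5e-4
        )

    def test_wstar_vanishes_with_heat_flux(self):
        assert convective_velocity_scale(1e-12, 1000.0, 293.15) == pytest.approx(
            0.0, abs=1e-3
        )

    def test_wstar_sentinel_for_stable_hours(self):
        assert convective_velocity_scale(-30.0, 800.0, 280.0) == MISSING
        assert convective_velocity_scale(0.0, 800.0, 280.0) == MISSING

    @given(H=st.floats(1.0, 500.0), zic=st.floats(10.0, 4000.0), t=st.floats(250.0, 320.0))
    def test_wstar_cube_root_homogeneity(self, H, zic, t):
        assert convective_velocity_scale(8 * H, zic, t) == pytest.approx(
            2 * convective_velocity_scale(H, zic, t), rel=1e-9
        )

    def test_obukhov_reference_value(self):
        # rho cp Tref u*^3 / (k g H) = 1.293*1004*293.15*0.027/(0.4*9.8*100)
        assert monin_obukhov_length(100.0, 0.3, 293.15) == pytest.approx(26.21, abs=0.01)

    def test_obukhov_zero_friction_velocity(self):
        assert monin_obukhov_length(50.0, 0.0, 293.15) == 0.0

    @given(H=st.floats(1.0, 500.0), u=st.floats(0.01, 2.0), t=st.floats(250.0, 320.0))
    def test_obukhov_sign_follows_heat_flux(self, H, u, t):
        assert monin_obukhov_length(H, u, t) > 0
        assert monin_obukhov_length(-H, u, t) < 0

    def test_obukhov_neutral_sentinel(self):
        assert monin_obukhov_length(1e-9, 0.5, 293.15) == NEUTRAL_OBUKHOV

    @pytest.mark.parametrize(
        "u, v, deg", [(0.0, 1.0, 180.0), (1.0, 0.0, 270.0), (1.0, 1.0, 225.0),
                      (0.0, -1.0, 0.0), (-1.0, 0.0, 90.0)]
    )
    def test_wind_direction_cardinals(self, u, v, deg):
        assert wind_direction(u, v) == pytest.approx(deg, abs=1e-9)

    def test_calm_wind_returns_zero(self):
        assert wind_direction(0.0, 0.0) == 0.0

    @given(u=finite.filter(lambda x: abs(x) < 1e6), v=finite.filter(lambda x: abs(x) < 1e6))
    def test_wind_direction_in_range(self, u, v):
        wd = wind_direction(u, v)
        assert 0.0 <= wd < 360.0

    @pytest.mark.parametrize(
        "down, up, regime, expected",
        [(500.0, 100.0, "CBL", 0.8), (100.0, 100.0, "CBL", 0.0),
         (500.0, 100.0, "SBL", 1.0), (0.0, 0.0, "SBL", 1.0)],
    )
    def test_albedo_cases(self, down, up, regime, expected):
        assert albedo(down, up, regime) == pytest.approx(expected)

    def test_albedo_daytime_without_sun_falls_back_to_one(self):
        assert albedo(0.0, 0.0, "CBL") == 1.0

    @given(down=st.floats(0.0, 1500.0), up=st.floats(0.0, 2000.0))
    def test_albedo_always_in_unit_interval(self, down, up):
        for regime in ("CBL", "SBL"):
            assert 0.0 <= albedo(down, up, regime) <= 1.0

    @pytest.mark.parametrize(
        "H, latent, med, expected",
        [(50.0, 100.0, 0.7, 0.5), (-50.0, 100.0, 0.7, 0.5), (50.0, 0.0, 0.7, 0.7)],
    )
    def test_bowen_ratio(self, H, latent, med, expected):
        assert bowen_ratio(H, latent, med) == pytest.approx(expected)

    @pytest.mark.parametrize("pct, decile", [(57.0, 5), (0.0, 0), (100.0, 10), (9.99, 0)])
    def test_cloud_cover_decile(self, pct, decile):
        assert cloud_cover_decile(pct) == decile

    def test_cloud_cover_out_of_range_clamped(self):
        assert cloud_cover_decile(130.0) == 10
        assert cloud_cover_decile(-5.0) == 0

    @given(pct=st.floats(0.0, 100.0))
    def test_cloud_decile_in_range(self, pct):
        assert 0 <= cloud_cover_decile(pct) <= 10

    def test_energy_balance_sensible_heat(self):
        # net radiation 430 minus ground 80 and latent 150
        assert sensible_heat_cbl(600.0, 120.0, 350.0, 400.0, 80.0, 150.0) == 200.0
        assert sensible_heat_cbl(0, 0, 0, 0, 0, 0) == 0.0
        assert sensible_heat_cbl(1200.0, 240.0, 700.0, 800.0, 160.0, 300.0) == 400.0


@pytest.fixture(scope="module")
def records(hourly_series):
    return build_scenario1(hourly_series)


class TestScenario1:

    def test_temperature_converted_to_kelvin(self, hourly_series, records):
        np.testing.assert_allclose(
            records["temperature"].to_numpy(),
            hourly_series["temperature_2m"].to_numpy() + 273.15,
        )

    def test_pressure_divided_by_ten(self, hourly_series, records):
        np.testing.assert_allclose(
            records["station_pressure"].to_numpy(),
            hourly_series["surface_pressure"].to_numpy() / 10.0,
        )

    def test_fixed_fields(self, records):
        assert (records["wind_height"] == 10.0).all()
        assert (records["temperature_height"] == 2.0).all()
        assert (records["precip_code"] == 11).all()
        assert (records["vptg_500m"] == -9.0).all()
        assert (records["adj_flag"] == "NAD").all()
        assert (records["sub_flag"] == "NoSubs").all()

    def test_albedo_is_one_in_stable_hours(self, records):
        assert (records.loc[records["regime"] == "SBL", "albedo"] == 1.0).all()

    def test_hour_ending_convention_with_utc_offset(self, hourly_series):
        rec = build_scenario1(hourly_series, tz_offset=-5)
        # first UTC hour (00:00 Jan 1) is local 19:00 Dec 31 -> hour 20 of day 365
        first = rec.iloc[0]
        assert first["hour"] == 20
        assert first["julian_day"] == 365
        assert first["year"] == 18
        assert set(rec["hour"]) <= set(range(1, 25))

    def test_missing_column_error_names_hrrr_variable(self, hourly_series):
        broken = hourly_series.drop(columns=["sensible_heat"])
        with pytest.raises(KeyError, match="Sensible heat net flux"):
            build_scenario1(broken)

    def test_closed_form_recovery(self, hourly_series, records):
        """Emitted w* and L equal the printed formulas to 6 significant digits."""
        H = hourly_series["sensible_heat"].to_numpy()
        tref = hourly_series["temperature_2m"].to_numpy() + 273.15
        zic = hourly_series["pbl_height"].to_numpy()
        ustar = hourly_series["friction_velocity"].to_numpy()
        conv = H > 0
        expect_w = (9.8 * H[conv] * zic[conv] / (1.293 * 1004.0 * tref[conv])) ** (1 / 3.0)
        expect_l = 1.293 * 1004.0 * tref * ustar**3 / (0.4 * 9.8 * H)
        np.testing.assert_allclose(records["w_star"].to_numpy()[conv], expect_w, rtol=1e-6)
        assert (records["w_star"].to_numpy()[~conv] == -9.0).all()
        np.testing.assert_allclose(records["obukhov_length"], expect_l, rtol=1e-6)


class TestScenario2:
    def test_raw_values_clamped(self, hourly_series):
        df = hourly_series.copy()
        df.iloc[0, df.columns.get_loc("sensible_heat")] = 1000.0
        df.iloc[1, df.columns.get_loc("pbl_height")] = 5200.0
        rec = apply_bounds_scenario2(df)
        assert rec.iloc[0]["sensible_heat"] == 800.0
        assert rec.iloc[1]["z_ic"] == 4000.0

    def test_identity_when_everything_inside_bounds(self, inbounds_series):
        s1 = build_scenario1(inbounds_series)
        s2 = apply_bounds_scenario2(inbounds_series)
        pd.testing.assert_frame_equal(s1, s2)

    def test_derived_values_recomputed_from_clamped_inputs(self, hourly_series):
        df = hourly_series.copy()
        i = int(np.argmax(df["visible_beam_downward_flux"].to_numpy()))
        df.iloc[i, df.columns.get_loc("sensible_heat")] = 2000.0
        rec = apply_bounds_scenario2(df)
        tref = df.iloc[i]["temperature_2m"] + 273.15
        zic = min(df.iloc[i]["pbl_height"], 4000.0)
        expect = min((9.8 * 800.0 * zic / (1.293 * 1004.0 * tref)) ** (1 / 3.0), 2.0)
        assert rec.iloc[i]["w_star"] == pytest.approx(expect, rel=1e-9)

    def test_input_clamping_idempotent(self, hourly_series):
        df = hourly_series.copy()
        df["sensible_heat"] += 600.0  # push some hours past the cap
        once = apply_input_bounds(df)
        pd.testing.assert_frame_equal(apply_input_bounds(once), once)

    def test_all_outputs_inside_bounds_under_fuzzing(self):
        cfg = SynthConfig(seed=13, n_days=60, outlier_rate=0.15)
        df = generate_hourly_series(cfg)[(0, 0)]
        rec = apply_bounds_scenario2(df)
        b = ScenarioBounds()
        assert rec["sensible_heat"].between(*b.sensible_heat).all()
        assert rec["friction_velocity"].between(*b.friction_velocity).all()
        assert rec["surface_roughness"].between(*b.surface_roughness).all()
        assert (rec["z_ic"] <= b.mixing_height_max).all()
        w = rec["w_star"]
        assert ((w == -9.0) | w.between(*b.w_star)).all()
        assert rec["obukhov_length"].between(*b.obukhov_length).all()
        assert rec["bowen_ratio"].between(*b.bowen).all()


class TestScenario3:
    def test_all_night_series_identical_to_scenario2(self):
        cfg = SynthConfig(seed=3, n_days=5, solar_peak=0.0)
        df = generate_hourly_series(cfg)[(0, 0)]
        assert (df["visible_beam_downward_flux"] == 0).all()
        pd.testing.assert_frame_equal(build_scenario3(df), apply_bounds_scenario2(df))

    def test_stable_hours_retain_scenario2_values(self, hourly_series):
        s2 = apply_bounds_scenario2(hourly_series)
        s3 = build_scenario3(hourly_series)
        night = s2["regime"] == "SBL"
        pd.testing.assert_frame_equal(s3.loc[night], s2.loc[night])

    def test_convective_hours_use_energy_balance(self, hourly_series):
        s3 = build_scenario3(hourly_series)
        day = s3["regime"] == "CBL"
        h = hourly_series.loc[day.to_numpy()]
        expect = np.clip(
            (h["downward_shortwave"] + h["downward_longwave"]
             - h["upward_shortwave"] - h["upward_longwave"])
            - h["ground_heat"] - np.clip(h["latent_heat"], -100.0, 800.0),
            -64.0, 800.0,
        )
        np.testing.assert_allclose(s3.loc[day, "sensible_heat"], expect)

    def test_energy_balance_heat_clamped_to_cap(self, hourly_series):
        df = hourly_series.copy()
        i = int(np.argmax(df["visible_beam_downward_flux"].to_numpy()))
        df.iloc[i, df.columns.get_loc("downward_shortwave")] = 2000.0
        df.iloc[i, df.columns.get_loc("upward_shortwave")] = 100.0
        rec = build_scenario3(df)
        assert rec.iloc[i]["sensible_heat"] == 800.0

    def test_only_daytime_heat_wstar_obukhov_differ_from_scenario2(self, inbounds_series):
        s2 = apply_bounds_scenario2(inbounds_series)
        s3 = build_scenario3(inbounds_series)
        same_cols = [c for c in s2.columns
                     if c not in ("sensible_heat", "w_star", "obukhov_length")]
        pd.testing.assert_frame_equal(s3[same_cols], s2[same_cols])
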