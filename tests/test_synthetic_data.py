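import numpy as np
import pandas as pd
import pytest

from fynhyd import micromet as m
from fynhyd import synthetic_data as sd
from fynhyd import vulnerability as v
from fynhyd.errors import AlignmentError, DomainError, InvalidConfigError


class TestWeatherGenerator:
    def test_rain_sums_to_target(self):
        w = sd.generate_weather(
            sd.WeatherConfig(season_length_days=90, summer_rain_total=90.0, seed=1)
        )
        assert w["rain"].sum() == pytest.approx(90.0, abs=0.9)

    def test_normal_season_with_large_events(self):
        w = sd.generate_weather(
            sd.WeatherConfig(
                season_length_days=90, summer_rain_total=253.0, n_large_events=3, seed=2
            )
        )
        assert w["rain"].sum() == pytest.approx(253.0, abs=2.53)
        daily = w.groupby(np.arange(len(w)) // 48)["rain"].sum()
        assert (daily > 20.0).sum() >= 3

    def test_zero_rain_config(self):
        w = sd.generate_weather(sd.WeatherConfig(summer_rain_total=0.0, seed=3))
        assert (w["rain"] == 0).all()

    def test_seed_reproducibility(self):
        cfg = sd.WeatherConfig(season_length_days=20, seed=4)
        w1 = sd.generate_weather(cfg)
        w2 = sd.generate_weather(cfg)
        pd.testing.assert_frame_equal(w1, w2)

    def test_invalid_season_length(self):
        with pytest.raises(InvalidConfigError):
            sd.WeatherConfig(season_length_days=0)

    def test_expected_record_count(self):
        w = sd.generate_weather(sd.WeatherConfig(season_length_days=10, seed=5))
        assert len(w) == 10 * 48

    def test_vpd_non_negative_everywhere(self, dry_season_weather):
        vpd = m.vpd(
            dry_season_weather["t_air"].to_numpy(), dry_season_weather["rh"].to_numpy()
        )
        assert np.all(vpd >= 0)

    def test_dew_frames_satisfy_detection_rule(self, dry_season_weather):
        w = dry_season_weather
        dew = w.loc[w["dew_truth"]]
        assert len(dew) > 0
        assert (dew["wetness_resistance"] < 400).all()
        assert (dew["rain"] == 0).all()
        tdew = m.dew_point(dew["t_air"].to_numpy(), dew["rh"].to_numpy())
        assert np.all(np.abs(dew["t_air"].to_numpy() - tdew) <= 0.5)


class TestSoilMoisture:
    def test_zero_rain_closed_form_decay(self):
        bucket = sd.BucketModel(capacity=30, residual=5, drainage_rate=0.1)
        rain = np.zeros(480)
        out = sd.generate_soil_moisture(rain, bucket)
        dt = 1 / 48
        t = (np.arange(480) + 1) * dt
        expected = 5 + (30 - 5) * np.exp(-0.1 * t)
        assert np.allclose(out.to_numpy(), expected)

    def test_bounded_between_residual_and_capacity(self):
        rng = np.random.default_rng(0)
        rain = rng.exponential(1.0, 2000)
        bucket = sd.BucketModel()
        out = sd.generate_soil_moisture(rain, bucket)
        assert out.min() >= bucket.residual - 1e-12
        assert out.max() <= bucket.capacity + 1e-12

    def test_monotone_decay_without_rain(self):
        rain = np.zeros(500)
        rain[100] = 10.0
        out = sd.generate_soil_moisture(rain, sd.BucketModel(capacity=40, residual=2))
        assert np.all(np.diff(out.to_numpy()[101:]) <= 0)
        assert np.all(np.diff(out.to_numpy()[:100]) <= 0)

    def test_single_pulse_matches_hand_recursion(self):
        bucket = sd.BucketModel(
            capacity=30, residual=5, infiltration_fraction=0.5, drainage_rate=0.2
        )
        rain = np.zeros(96)
        rain[50] = 12.0
        out = sd.generate_soil_moisture(rain, bucket, initial=20.0)
        # hand-integrated recursion
        dt = 1 / 48
        s = 20.0
        expected = []
        for r in rain:
            s = 5 + (s - 5) * np.exp(-0.2 * dt)
            s = min(s + 0.5 * r, 30.0)
            expected.append(s)
        assert np.allclose(out.to_numpy(), expected)
        assert out.iloc[50] - out.iloc[49] > 5.0  # step increase at the pulse

    def test_degenerate_capacity_equals_residual(self):
        bucket = sd.BucketModel(capacity=10, residual=10)
        out = sd.generate_soil_moisture(np.ones(20), bucket)
        assert (out == 10).all()

    def test_residual_above_capacity_rejected(self):
        with pytest.raises(InvalidConfigError):
            sd.BucketModel(capacity=5, residual=10)

    def test_negative_rain_rejected(self):
        with pytest.raises(DomainError):
            sd.generate_soil_moisture(np.array([-1.0]), sd.BucketModel())


def _dry_spell_scenario(seed=13, pulse_day=60, pulse_mm=8.0):
    """Long rainless drydown with one small late pulse."""
    cfg = sd.WeatherConfig(
        season_length_days=75,
        summer_rain_total=0.0,
        dew_probability_per_night=0.0,
        seed=seed,
    )
    w = sd.generate_weather(cfg)
    rain = np.zeros(len(w))
    rain[pulse_day * 48 + 30] = pulse_mm
    w = w.copy()
    w["rain"] = rain
    soil = sd.generate_soil_layers(
        pd.Series(rain, index=pd.DatetimeIndex(w["timestamp"]))
    )
    return w, soil, pd.Timestamp(w["timestamp"].iloc[pulse_day * 48])


class TestPlantSeries:
    def test_ericoid_responds_to_small_pulse(self):
        w, soil, pulse_date = _dry_spell_scenario()
        arch = sd.SpeciesArchetype(
            name="ericoid",
            rooting_depth_weighting=1.0,
            vpd_sensitivity=0.5,
            soil_sensitivity=1.5,
            dew_use_fraction=0.0,
            max_vh=0.02,
            psi_min_dry=-4.0,
            vulnerability_a=-1.51,
            vulnerability_b=-5.68,
        )
        plant = sd.generate_plant_series(arch, w, soil, seed=1)
        ratio = sd.pulse_response_ratio(plant.vh, pulse_date)
        assert ratio >= 5.0

    def test_proteoid_barely_responds_to_small_pulse(self):
        w, soil, pulse_date = _dry_spell_scenario()
        plant = sd.generate_plant_series(sd.PROTEOID, w, soil, seed=1)
        ratio = sd.pulse_response_ratio(plant.vh, pulse_date)
        assert ratio < 1.4

    def test_min_predawn_reaches_configured_floor(self):
        w, soil, _ = _dry_spell_scenario(pulse_mm=0.0)
        plant = sd.generate_plant_series(sd.ERICOID, w, soil, seed=2, psi_noise_sd=0.02)
        predawn = plant.psi.loc[plant.psi["period"] == "predawn", "psi"]
        assert predawn.min() == pytest.approx(sd.ERICOID.psi_min_dry, abs=0.2)

    def test_zero_max_vh_gives_zero_flow(self):
        w, soil, _ = _dry_spell_scenario()
        arch = sd.SpeciesArchetype(
            name="null",
            rooting_depth_weighting=1.0,
            vpd_sensitivity=0.5,
            soil_sensitivity=1.0,
            dew_use_fraction=0.0,
            max_vh=0.0,
            psi_min_dry=-1.0,
            vulnerability_a=-1.0,
            vulnerability_b=-1.0,
        )
        plant = sd.generate_plant_series(arch, w, soil, seed=3)
        assert (plant.vh == 0).all()

    def test_predawn_never_below_midday(self, dry_season_weather):
        w = dry_season_weather
        soil = sd.generate_soil_layers(
            pd.Series(w["rain"].to_numpy(), index=pd.DatetimeIndex(w["timestamp"]))
        )
        for arch in (sd.ERICOID, sd.PROTEOID, sd.RESTIOID):
            plant = sd.generate_plant_series(arch, w, soil, seed=4)
            wide = plant.psi.pivot_table(
                index=["date", "individual_id"], columns="period", values="psi"
            )
            assert (wide["predawn"] >= wide["midday"]).all()

    def test_archetype_midday_ordering_dry_season(self, dry_season_weather):
        w = dry_season_weather
        soil = sd.generate_soil_layers(
            pd.Series(w["rain"].to_numpy(), index=pd.DatetimeIndex(w["timestamp"]))
        )
        minima = {}
        for arch in (sd.ERICOID, sd.PROTEOID, sd.RESTIOID):
            plant = sd.generate_plant_series(arch, w, soil, seed=5)
            minima[arch.name] = plant.psi.loc[
                plant.psi["period"] == "midday", "psi"
            ].min()
        assert minima["ericoid"] < minima["restioid"]
        assert minima["ericoid"] < minima["proteoid"]

    def test_vh_positively_associated_with_soil_moisture(self, dry_season_weather):
        w = dry_season_weather
        soil = sd.generate_soil_layers(
            pd.Series(w["rain"].to_numpy(), index=pd.DatetimeIndex(w["timestamp"]))
        )
        plant = sd.generate_plant_series(sd.ERICOID, w, soil, seed=6)
        daily_vh = plant.vh.groupby(pd.DatetimeIndex(plant.vh.index).normalize()).sum()
        daily_soil = soil["shallow"].groupby(soil.index.normalize()).mean()
        r = np.corrcoef(daily_vh.to_numpy(), daily_soil.to_numpy())[0, 1]
        assert r > 0.3

    def test_misaligned_time_bases_rejected(self, short_weather):
        soil = pd.DataFrame(
            {"shallow": np.ones(10), "deep": np.ones(10)},
            index=pd.date_range("2013-12-01", periods=10, freq="30min"),
        )
        with pytest.raises(AlignmentError):
            sd.generate_plant_series(sd.ERICOID, short_weather, soil)

    def test_reproducible(self, short_weather):
        soil = sd.generate_soil_layers(
            pd.Series(
                short_weather["rain"].to_numpy(),
                index=pd.DatetimeIndex(short_weather["timestamp"]),
            )
        )
        p1 = sd.generate_plant_series(sd.RESTIOID, short_weather, soil, seed=7)
        p2 = sd.generate_plant_series(sd.RESTIOID, short_weather, soil, seed=7)
        pd.testing.assert_series_equal(p1.vh, p2.vh)
        pd.testing.assert_frame_equal(p1.psi, p2.psi)


class TestOpticalStack:
    def test_vessel_pixels_flip_exactly_once(self):
        synth = sd.generate_optical_stack(
            sd.SyntheticStackConfig(n_vessels=20, noise_sd=0.0, seed=1)
        )
        frames = synth.stack.frames.astype(int)
        changes = np.abs(np.diff(frames, axis=0)).astype(bool)
        n_changes = changes.sum(axis=0)
        vessel_px = synth.vessel_masks.any(axis=0)
        assert np.all(n_changes[vessel_px] == 1)
        assert np.all(n_changes[~vessel_px] == 0)

    def test_flip_frame_matches_schedule_crossing(self):
        cfg = sd.SyntheticStackConfig(n_vessels=30, noise_sd=0.0, seed=2)
        synth = sd.generate_optical_stack(cfg)
        schedule = synth.timeline.psi
        frames = synth.stack.frames
        for i in range(cfg.n_vessels):
            mask = synth.vessel_masks[i]
            flips = np.flatnonzero(
                np.diff(frames[:, mask][:, 0].astype(int)) != 0
            )
            assert len(flips) == 1
            k = flips[0] + 1  # frame where the vessel first shows embolized
            psi_v = synth.vessel_psi[i]
            if schedule[-1] <= psi_v <= schedule[0]:
                expected = int(np.argmax(schedule <= psi_v))
                assert k == max(expected, 1)

    def test_single_vessel_step_curve(self):
        synth = sd.generate_optical_stack(
            sd.SyntheticStackConfig(n_vessels=1, noise_sd=0.0, seed=3)
        )
        diff = v.difference_images(synth.stack)
        events = v.detect_embolism_events(diff, intensity_threshold=0.1)
        cum = v.cumulative_embolism(events)
        assert set(np.round(cum.to_numpy(), 9)) <= {0.0, 100.0}
        assert cum.iloc[-1] == 100.0

    def test_final_frame_all_vessels_embolized(self):
        synth = sd.generate_optical_stack(
            sd.SyntheticStackConfig(n_vessels=50, noise_sd=0.0, seed=4)
        )
        last = synth.stack.frames[-1]
        vessel_px = synth.vessel_masks.any(axis=0)
        assert np.all(last[vessel_px] == synth.config.embolized_grey)

    def test_percent_embolism_matches_sigmoid_within_sampling_error(self):
        cfg = sd.SyntheticStackConfig(
            n_vessels=100, vulnerability_a=-2.0, vulnerability_b=-3.0, noise_sd=0.0, seed=5
        )
        synth = sd.generate_optical_stack(cfg)
        # brute force from drawn vessel potentials
        for psi in (-1.0, -2.0, -3.0, -4.0, -5.0):
            emp = np.mean(synth.vessel_psi >= psi) * 100
            theo = v.sigmoid_percent_embolism(psi, -2.0, -3.0)
            se = np.sqrt(theo / 100 * (1 - theo / 100) / cfg.n_vessels) * 100
            assert emp == pytest.approx(theo, abs=max(4 * se, 1.0))

    def test_same_seed_identical_stacks(self):
        cfg = sd.SyntheticStackConfig(n_vessels=10, noise_sd=3.0, seed=6)
        s1 = sd.generate_optical_stack(cfg)
        s2 = sd.generate_optical_stack(cfg)
        assert np.array_equal(s1.stack.frames, s2.stack.frames)
        assert np.array_equal(s1.vessel_psi, s2.vessel_psi)

    def test_non_monotone_schedule_rejected(self):
        with pytest.raises(InvalidConfigError):
            sd.SyntheticStackConfig(psi_start=-5.0, psi_end=-1.0)

    def test_zero_vessels_rejected(self):
        with pytest.raises(InvalidConfigError):
            sd.SyntheticStackConfig(n_vessels=0)


class TestFixtureWriters:
    def test_weather_csv_roundtrip(self, tmp_path, short_weather):
        path = sd.write_weather_csv(short_weather, tmp_path / "weather.csv")
        back = pd.read_csv(path, parse_dates=["timestamp"])
        assert len(back) == len(short_weather)
        assert np.allclose(back["rain"], short_weather["rain"])

    def test_stack_writer_roundtrip(self, tmp_path):
        import tifffile

        synth = sd.generate_optical_stack(
            sd.SyntheticStackConfig(n_vessels=5, image_shape=(40, 40), seed=9)
        )
        out = sd.write_stack(synth, tmp_path / "stack")
        manifest = pd.read_csv(out / "manifest.csv")
        assert len(manifest) == synth.stack.n_frames
        first = tifffile.imread(out / manifest["filename"].iloc[0])
        assert np.array_equal(first, synth.stack.frames[0])
        tl = pd.read_csv(out / "psi_timeline.csv")
        assert np.allclose(tl["psi"], synth.timeline.psi)
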