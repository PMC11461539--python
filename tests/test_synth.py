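import numpy as np
import pandas as pd
import pytest

from pivotwdi.errors import ValidationError
from pivotwdi.pipeline import (aggregate_plot_observations, assign_readings,
                               compute_field_wdi)
from pivotwdi.synth import (NoiseConfig, SeasonConfig, generate_field_layout,
                            generate_weather, synthesize_canopy_raster,
                            synthesize_sensor_pass)


class TestWeatherGenerator:
    def test_same_seed_is_bitwise_identical(self):
        cfg = SeasonConfig(days=30)
        d1, h1 = generate_weather(cfg, 123)
        d2, h2 = generate_weather(cfg, 123)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(h1, h2)
        d3, _ = generate_weather(cfg, 124)
        assert not d1.ta_c.equals(d3.ta_c)

    def test_humidity_stays_physical(self):
        _, hourly = generate_weather(SeasonConfig(days=1500), 2)
        assert len(hourly) >= 10000
        assert hourly.rh_pct.between(0.0, 100.0).all()
        assert (hourly.rs_wm2 >= 0).all()

    def test_season_mean_temperature_matches_config(self):
        """The seasonal cycle is built with zero mean, so the long-run sample
        mean converges on the configured season mean."""
        cfg = SeasonConfig(days=3000, ta_mean_c=27.0)
        daily, _ = generate_weather(cfg, 7)
        assert daily.ta_c.mean() == pytest.approx(27.0, abs=0.5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            generate_weather(SeasonConfig(days=3), 0)
        with pytest.raises(ValidationError):
            generate_weather(SeasonConfig(rain_prob=1.5), 0)


class TestLayout:
    def test_slices_partition_half_circle(self):
        layout = generate_field_layout(0)
        plots = layout.plots.sort_values("theta_start")
        assert np.allclose(plots.theta_end - plots.theta_start, 15.0)
        assert plots.theta_start.iloc[0] == 0.0
        assert plots.theta_end.iloc[-1] == 180.0
        assert np.allclose(plots.theta_start.iloc[1:].to_numpy(),
                           plots.theta_end.iloc[:-1].to_numpy())

    def test_randomized_complete_block_structure(self):
        layout = generate_field_layout(4)
        by_block = layout.plots.groupby("block").treatment
        for _, treatments in by_block:
            assert sorted(treatments) == [0.0, 0.30, 0.60, 0.90]
        counts = layout.plots.treatment.value_counts()
        assert (counts == 3).all()

    def test_layout_deterministic_under_seed(self):
        pd.testing.assert_frame_equal(generate_field_layout(9).plots,
                                      generate_field_layout(9).plots)

    def test_bearing_lookup_half_open(self):
        layout = generate_field_layout(0)
        assert layout.plot_at(7.0) == 1
        assert layout.plot_at(15.0) == 2  # boundary belongs to the next slice
        assert layout.plot_at(200.0) is None


class TestTruth:
    def test_treatment_stress_ordering(self, zero_noise_season):
        means = zero_noise_season.truth.groupby("treatment").wdi_true.mean()
        assert means[0.90] <= means[0.60] <= means[0.30] <= means[0.0]

    def test_unwatered_plot_reaches_full_stress(self):
        cfg = SeasonConfig(days=120, rain_prob=0.0)
        from pivotwdi.synth import simulate_truth
        from pivotwdi.waterbalance import KcCurve, SoilProfile
        daily, _ = generate_weather(cfg, 3)
        layout = generate_field_layout(3, cfg)
        truth, _, _ = simulate_truth(layout, daily, SoilProfile(), KcCurve(), 3)
        dryland = truth[(truth.treatment == 0.0) & (truth.dap > 100)]
        assert dryland.wdi_true.min() > 0.95

    def test_canopy_growth_nondecreasing(self, zero_noise_season):
        for _, grp in zero_noise_season.truth.groupby("plot"):
            fc = grp.sort_values("dap").fc.to_numpy()
            assert np.all(np.diff(fc) >= -1e-12)
            assert fc.max() <= 0.98


class TestSensorPass:
    def test_zero_noise_round_trip(self, zero_noise_season):
        """Noiseless pass -> pipeline recovers the truth table exactly."""
        s = zero_noise_season
        day = s.pass_dates[len(s.pass_dates) // 2]
        readings = s.readings[s.readings.date == day]
        labeled, _ = assign_readings(readings, s.layout)
        obs = aggregate_plot_observations(labeled, s.layout)
        res = compute_field_wdi(obs, s.hourly, s.layout)
        merged = res.merge(s.truth, on=["plot", "date"])
        assert len(merged) == 12
        assert np.abs(merged.wdi - merged.wdi_true).max() < 1e-9

    def test_same_seed_identical_trace(self, noisy_season):
        s = noisy_season
        day = s.pass_dates[0]
        a = synthesize_sensor_pass(s.truth, s.layout, s.hourly, day,
                                   NoiseConfig(), seed=55)
        b = synthesize_sensor_pass(s.truth, s.layout, s.hourly, day,
                                   NoiseConfig(), seed=55)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_does_not_bias_recovered_wdi(self, noisy_season):
        """Additive symmetric Ts noise leaves the per-plot WDI unbiased
        (the index is linear in Ts inside the trapezoid); checked against
        the Monte-Carlo standard error over 150 seeded passes."""
        s = noisy_season
        day = s.pass_dates[len(s.pass_dates) // 2]
        truth_day = s.truth[s.truth.date == day].set_index("plot")
        interior = truth_day[(truth_day.wdi_true > 0.2) & (truth_day.wdi_true < 0.8)]
        assert len(interior) > 0
        plots = interior.index.to_list()
        n_passes = 150
        errs = {p: [] for p in plots}
        for k in range(n_passes):
            pass_df = synthesize_sensor_pass(s.truth, s.layout, s.hourly, day,
                                             NoiseConfig(sigma_ts_c=0.5,
                                                         sigma_ndvi=0.0),
                                             seed=10_000 + k)
            labeled, _ = assign_readings(pass_df, s.layout)
            obs = aggregate_plot_observations(labeled, s.layout)
            res = compute_field_wdi(obs, s.hourly, s.layout).set_index("plot")
            for p in plots:
                errs[p].append(res.loc[p, "wdi"] - interior.loc[p, "wdi_true"])
        for p in plots:
            e = np.asarray(errs[p])
            se = e.std(ddof=1) / np.sqrt(n_passes)
            assert abs(e.mean()) < 4 * se + 1e-4


class TestCanopyRaster:
    def test_constructed_fraction_recovered(self):
        from pivotwdi.canopy import otsu_canopy_cover
        raster = synthesize_canopy_raster(0.40, (50, 50), seed=1)
        _, fc = otsu_canopy_cover(raster)
        assert fc == pytest.approx(0.40, abs=1.0 / 2500 + 1e-12)

    def test_zero_cover_is_degenerate_single_class(self):
        from pivotwdi.canopy import otsu_canopy_cover
        raster = synthesize_canopy_raster(0.0, (16, 16), seed=0)
        with pytest.raises(ValidationError):
            otsu_canopy_cover(raster)

    def test_deterministic_and_shape_checked(self):
        a = synthesize_canopy_raster(0.3, (12, 12), seed=8)
        b = synthesize_canopy_raster(0.3, (12, 12), seed=8)
        assert np.array_equal(a, b)
        with pytest.raises(ValidationError):
            synthesize_canopy_raster(0.3, (5, 40), seed=0)
        with pytest.raises(ValidationError):
            synthesize_canopy_raster(1.3, (12, 12), seed=0)
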