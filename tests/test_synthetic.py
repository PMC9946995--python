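"""Synthetic landscape generator: rainfall, dynamics, rendering, surveys."""

import numpy as np
import pytest

from rangeres import spectral, synthetic
from rangeres.synthetic import (
    CoverSeries,
    WorldConfig,
    cover_step,
    generate_world,
    make_truth,
    render_year,
    sample_survey_plots,
    simulate_cover_dynamics,
    simulate_rainfall,
    stratify_sites,
)


class TestWorldConfig:
    def test_shock_years_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            WorldConfig(years=(2000, 2001), shock_years=(1990,))

    def test_cloud_prob_bounds(self):
        with pytest.raises(ValueError, match="cloud_prob"):
            WorldConfig(cloud_prob=1.5)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            WorldConfig(dynamics_sd=-0.1)


class TestRainfall:
    def test_shock_year_deficit_parameterization(self):
        # no noise sources: shock-year total is exactly mean * (1 - deficit)
        cfg = WorldConfig(
            grid_rows=7, grid_cols=7, rain_rows=1, rain_cols=1,
            rain_sd_mm=0, rain_gradient_sd_mm=0, rain_cell_sd_mm=0,
            years=(2000, 2001, 2002), shock_years=(2001,), shock_deficit=0.5,
        )
        rain = simulate_rainfall(cfg)
        totals = rain.annual_totals()
        assert np.allclose(totals[rain.year_index(2001)], 300.0)
        assert np.allclose(totals[rain.year_index(2000)], 600.0)

    def test_deterministic_under_seed(self):
        cfg = WorldConfig(grid_rows=7, grid_cols=7, seed=11)
        a = simulate_rainfall(cfg)
        b = simulate_rainfall(cfg)
        np.testing.assert_array_equal(a.monthly, b.monthly)

    def test_monte_carlo_mean_recovers_parameter(self):
        # 21 years, no shocks, common-year sd 60: cell-mean of yearly totals
        # within 3 standard errors of the 600 mm parameter
        cfg = WorldConfig(
            grid_rows=7, grid_cols=7, rain_rows=1, rain_cols=1,
            shock_years=(), rain_sd_mm=60, rain_gradient_sd_mm=0, rain_cell_sd_mm=0,
            seed=5,
        )
        totals = simulate_rainfall(cfg).annual_totals()[1:]  # study years
        se = 60 / np.sqrt(totals.shape[0])
        assert abs(totals.mean() - 600.0) < 3 * se

    def test_empty_years_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(years=())

    def test_covers_previous_year(self):
        cfg = WorldConfig(grid_rows=7, grid_cols=7, years=(2005, 2006), shock_years=())
        rain = simulate_rainfall(cfg)
        assert rain.years[0] == 2004

    def test_monthly_profile_sums_to_annual_total(self):
        cfg = WorldConfig(grid_rows=7, grid_cols=7, seed=3)
        rain = simulate_rainfall(cfg)
        assert np.all(rain.monthly >= 0)
        np.testing.assert_allclose(rain.monthly.sum(axis=1), rain.annual_totals())


class TestCoverStep:
    def test_frozen_dynamics_hold_baseline(self):
        b = cover_step(0.3, anomaly=-2.0, susceptibility=0.0, recovery_rate=0.0, baseline=0.3)
        assert b == pytest.approx(0.3)

    def test_single_shock_arithmetic(self):
        # A = -2, delta = 0.1: bare ground rises by exactly 0.2
        b = cover_step(0.3, anomaly=-2.0, susceptibility=0.1, recovery_rate=0.5, baseline=0.3)
        assert b == pytest.approx(0.5, abs=1e-15)

    def test_full_recovery_in_one_wet_year(self):
        # rho = 1 with A = +1 removes the whole excess over baseline
        b = cover_step(0.5, anomaly=1.0, susceptibility=0.1, recovery_rate=1.0, baseline=0.3)
        assert b == pytest.approx(0.3, abs=1e-15)

    def test_clipping_to_unit_interval(self):
        assert cover_step(0.95, -2.0, 0.1, 0.5, 0.3) == 1.0


class TestCoverDynamics:
    def test_frozen_world_stays_at_baseline(self, tiny_config):
        truth = make_truth(tiny_config)
        truth.susceptibility[:] = 0
        truth.recovery_rate[:] = 0
        import dataclasses

        cfg = dataclasses.replace(tiny_config, dynamics_sd=0.0, pressure_scale=0.0)
        rain = simulate_rainfall(cfg)
        cover = simulate_cover_dynamics(truth, rain, cfg)
        for t in range(cover.cover.shape[0]):
            np.testing.assert_allclose(cover.cover[t], truth.baseline)

    def test_matches_per_pixel_loop_oracle(self, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, dynamics_sd=0.0)
        truth = make_truth(cfg)
        rain = simulate_rainfall(cfg)
        cover = simulate_cover_dynamics(truth, rain, cfg)

        # independent scalar re-implementation of the documented update rule
        anom = rain.anomalies(cfg.years)
        prow, pcol = synthetic._cell_of_pixel(cfg)
        w_d = np.array([cfg.w_designation[d] for d in synthetic.DESIGNATIONS])
        for (i, j) in [(0, 0), (5, 17), (27, 3)]:
            press = cfg.pressure_scale * (
                cfg.w_human * truth.human_density[i, j]
                + cfg.w_livestock * truth.livestock_density[i, j]
                + w_d[truth.designation[i, j]]
            )
            beta = truth.baseline[i, j]
            delta = truth.susceptibility[i, j]
            rho = truth.recovery_rate[i, j]
            b = beta
            for t in range(len(cfg.years)):
                A = anom[t, prow[i], pcol[j]]
                b = b + delta * max(0.0, -A) - rho * (b - beta) * max(0.0, A) + press
                b = min(max(b, 0.0), 1.0)
                assert b == pytest.approx(cover.cover[t, i, j], abs=1e-12)

    def test_invalid_recovery_rate_rejected(self, tiny_config):
        truth = make_truth(tiny_config)
        truth.recovery_rate[0, 0] = 1.5
        with pytest.raises(ValueError, match="recovery_rate"):
            synthetic.PixelTruth(**{f: getattr(truth, f) for f in (
                "baseline", "susceptibility", "recovery_rate", "phase",
                "human_density", "livestock_density", "designation")})


class TestRenderScenes:
    def test_pure_soil_limit(self, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, reflectance_sd=0.0, cloud_prob=0.0)
        truth = make_truth(cfg)
        cover = CoverSeries(np.array([2016]), np.ones((1,) + cfg.shape))
        scenes = render_year(cover, truth, cfg, 2016)
        for s in scenes:
            for band, em in zip((s.blue, s.red, s.nir, s.swir), cfg.soil_endmember):
                np.testing.assert_allclose(band, em)

    def test_no_clouds_all_valid(self, tiny_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_config, cloud_prob=0.0)
        truth = make_truth(cfg)
        cover = CoverSeries(np.array([2016]), np.full((1,) + cfg.shape, 0.3))
        assert all(s.valid.all() for s in render_year(cover, truth, cfg, 2016))

    def test_cloud_fraction_binomial(self):
        cfg = WorldConfig(grid_rows=35, grid_cols=35, cloud_prob=0.1, seed=2)
        truth = make_truth(cfg)
        cover = CoverSeries(np.array([2016]), np.full((1,) + cfg.shape, 0.3))
        scenes = render_year(cover, truth, cfg, 2016)
        n = sum(s.valid.size for s in scenes)  # 12 * 1225 = 14700 pixel-scenes
        invalid = sum((~s.valid).sum() for s in scenes) / n
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(invalid - 0.1) < 3 * se

    def test_bad_endmembers_rejected(self):
        with pytest.raises(ValueError, match="endmember"):
            WorldConfig(soil_endmember=(1.2, 0.2, 0.3, 0.3))

    def test_indices_monotone_in_bare_ground(self, tiny_config):
        # noiseless ladder: BSI increases with bare ground, EVI/MSAVI decrease
        import dataclasses

        cfg = dataclasses.replace(tiny_config, reflectance_sd=0.0, cloud_prob=0.0)
        truth = make_truth(cfg)
        ladder = [0.0, 0.25, 0.5, 0.75, 1.0]
        bsi, evi, msavi = [], [], []
        for b in ladder:
            cover = CoverSeries(np.array([2016]), np.full((1,) + cfg.shape, b))
            scene = render_year(cover, truth, cfg, 2016)[3]
            bsi.append(np.nanmean(spectral.compute_bsi(scene)))
            evi.append(np.nanmean(spectral.compute_evi(scene)))
            msavi.append(np.nanmean(spectral.compute_msavi(scene)))
        assert np.all(np.diff(bsi) > 0)
        assert np.all(np.diff(evi) < 0)
        assert np.all(np.diff(msavi) < 0)


class TestStratify:
    def test_at_most_eight_strata_for_2x2x2(self):
        rng = np.random.default_rng(0)
        labels = stratify_sites(rng.random((10, 10)), rng.random((10, 10)), rng.integers(0, 2, (10, 10)))
        assert len(np.unique(labels)) <= 8

    def test_constant_layers_single_stratum(self):
        ones = np.ones((5, 5))
        with pytest.warns(UserWarning, match="constant"):
            labels = stratify_sites(ones, ones, np.zeros((5, 5), dtype=int))
        assert len(np.unique(labels)) == 1

    def test_rainfall_quantiles_separate_strata(self):
        rain = np.linspace(0, 1, 100).reshape(10, 10)
        green = np.full((10, 10), 0.5)
        land = np.zeros((10, 10), dtype=int)
        with pytest.warns(UserWarning):
            labels = stratify_sites(rain, green, land)
        assert labels.ravel()[10] != labels.ravel()[90]


class TestSurveyPlots:
    def _uniform_world(self, b, n=70):
        cover = CoverSeries(np.array([2016]), np.full((1, n, n), float(b)))
        strata = np.zeros((n // 2, n // 2), dtype=int)
        return cover, strata

    def test_zero_cover_measures_zero(self):
        cover, strata = self._uniform_world(0.0)
        plots = sample_survey_plots(cover, strata, 50, [2016], seed=0, cell_size=2)
        assert (plots["bare_points"] == 0).all()

    def test_binomial_mean_unbiased(self):
        cover, strata = self._uniform_world(0.4, n=180)
        plots = sample_survey_plots(cover, strata, 1000, [2016], seed=1, cell_size=2)
        se = np.sqrt(0.4 * 0.6 / 100) / np.sqrt(len(plots))
        assert abs(plots["bare_fraction"].mean() - 0.4) < 3 * se

    def test_even_allocation_across_strata(self):
        cover, _ = self._uniform_world(0.3)
        strata = np.repeat(np.arange(3), 35 * 35 // 3 + 1)[: 35 * 35].reshape(35, 35)
        plots = sample_survey_plots(cover, strata, 9, [2016], seed=0, cell_size=2)
        assert plots.groupby("stratum").size().tolist() == [3, 3, 3]

    def test_no_adjacent_cells(self):
        cover, strata = self._uniform_world(0.3)
        plots = sample_survey_plots(cover, strata, 100, [2016], seed=3, cell_size=2)
        cells = plots[["cell_row", "cell_col"]].to_numpy()
        for i in range(len(cells)):
            d = np.abs(cells - cells[i]).max(axis=1)
            assert (d[np.arange(len(cells)) != i] > 1).all()

    def test_over_requesting_errors(self):
        cover, strata = self._uniform_world(0.3, n=8)
        with pytest.raises(ValueError, match="non-adjacent"):
            sample_survey_plots(cover, strata, 16, [2016], seed=0, cell_size=2)


def test_world_generation_bit_deterministic(tiny_config):
    a = generate_world(tiny_config, "loss_of_recovery")
    b = generate_world(tiny_config, "loss_of_recovery")
    np.testing.assert_array_equal(a["cover"].cover, b["cover"].cover)
    np.testing.assert_array_equal(a["truth"].recovery_rate, b["truth"].recovery_rate)
    np.testing.assert_array_equal(a["rainfall"].monthly, b["rainfall"].monthly)


def test_presets_differ_only_in_dynamics_fields(tiny_config):
    res = make_truth(tiny_config, "loss_of_resistance")
    rec = make_truth(tiny_config, "loss_of_recovery")
    np.testing.assert_array_equal(res.baseline, rec.baseline)
    np.testing.assert_array_equal(res.designation, rec.designation)
    assert np.ptp(res.susceptibility) > 0 and np.ptp(res.recovery_rate) == 0
    assert np.ptp(rec.susceptibility) == 0 and np.ptp(rec.recovery_rate) > 0


def test_unknown_scenario_rejected(tiny_config):
    with pytest.raises(ValueError, match="scenario"):
        make_truth(tiny_config, "loss_of_everything")
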