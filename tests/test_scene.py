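"""Synthetic scene generator: determinism, known moments, calibrated prevalence,
label sampling, NDVI trajectories and climate-statistic semantics."""

import dataclasses

import numpy as np
import pytest

from wiltscan import (
    compute_climate_statistics,
    compute_wilting_probability,
    generate_drivers,
    generate_ndvi_series,
    generate_scene,
    sample_labels,
)
from wiltscan.scene import (
    CLASS_FOREST,
    DOY_MAY1,
    DOY_SEP30,
    Phenology,
    SceneConfig,
    WINDOW_EARLY_SUMMER_Y1,
    WINDOW_EARLY_SUMMER_Y2,
)


class TestDrivers:
    def test_deterministic_given_seed(self, small_config):
        a = generate_drivers(small_config)
        b = generate_drivers(small_config)
        for name in a.names:
            np.testing.assert_array_equal(a[name], b[name])
        np.testing.assert_array_equal(a.forest_mask, b.forest_mask)
        np.testing.assert_array_equal(a.artifact_class, b.artifact_class)

    def test_white_noise_moments_without_smoothing(self):
        # unsmoothed, unclipped driver must match its stated mean/sd (3-SE bounds)
        cfg = SceneConfig(grid_rows=100, grid_cols=100, smoothing_length=0.0, seed=21)
        d = generate_drivers(cfg)
        from wiltscan.scene import DRIVER_SPECS

        for name in ("aug_tmax", "aug_tmax_anom"):
            mean, sd, *_ = DRIVER_SPECS[name]
            x = d[name].ravel()
            n = x.size
            assert abs(x.mean() - mean) < 3 * sd / np.sqrt(n)
            assert abs(x.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * n)

    def test_forest_fraction_matches_artifact_fraction(self, small_config, small_scene):
        drivers, _, _ = small_scene
        n = drivers.forest_mask.size
        frac = drivers.forest_mask.mean()
        p = 1 - small_config.artifact_fraction
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SceneConfig(grid_rows=0)
        with pytest.raises(ValueError):
            SceneConfig(grid_rows=10, grid_cols=10, coarse_factor=50)


class TestWiltingProbability:
    def test_null_link_gives_constant_half(self, small_scene):
        drivers, _, _ = small_scene
        p = compute_wilting_probability(drivers, {}, prevalence_target=0.5)
        np.testing.assert_allclose(p[drivers.forest_mask], 0.5, atol=1e-3)

    def test_monotone_in_single_positive_effect(self, small_scene):
        drivers, _, _ = small_scene
        p = compute_wilting_probability(drivers, {"aug_tmax_anom": (1.0, 0.0)}, 0.3)
        x = drivers["aug_tmax_anom"][drivers.forest_mask]
        order = np.argsort(x)
        pp = p[drivers.forest_mask][order]
        assert np.all(np.diff(pp) >= -1e-12)

    def test_default_prevalence_calibration(self, small_scene, small_config):
        drivers, truth, _ = small_scene
        mean_p = np.nanmean(truth.probability[drivers.forest_mask])
        assert abs(mean_p - small_config.prevalence_target) < 1e-3

    def test_unknown_driver_rejected(self, small_scene):
        drivers, _, _ = small_scene
        with pytest.raises(KeyError):
            compute_wilting_probability(drivers, {"no_such_driver": (1.0, 0.0)}, 0.1)


class TestLabels:
    @pytest.mark.parametrize("const_p,expected", [(0.0, "none"), (1.0, "all")])
    def test_degenerate_probabilities(self, small_scene, small_config, const_p, expected):
        drivers, _, _ = small_scene
        p = np.full(drivers.shape, const_p)
        p[~drivers.forest_mask] = np.nan
        truth = sample_labels(p, drivers, small_config)
        true_forest = drivers.forest_mask & (drivers.artifact_class == CLASS_FOREST)
        if expected == "none":
            assert truth.wilted_count == 0
        else:
            assert truth.labels[true_forest].all()
            assert not truth.labels[~true_forest].any()

    def test_binomial_count_bound(self, small_scene, small_config):
        drivers, _, _ = small_scene
        p = np.full(drivers.shape, 0.1)
        truth = sample_labels(p, drivers, small_config)
        n = int((drivers.forest_mask & (drivers.artifact_class == CLASS_FOREST)).sum())
        assert abs(truth.wilted_count - 0.1 * n) <= 3 * np.sqrt(n * 0.1 * 0.9)

    def test_onset_within_window_and_area_identity(self, small_scene, small_config):
        _, truth, _ = small_scene
        d0, d1 = small_config.wilt_onset_window
        on = truth.onset_day[truth.labels]
        assert np.all((on >= d0) & (on <= d1))
        assert truth.wilted_area_m2 == truth.wilted_count * small_config.pixel_size**2

    def test_conservation_of_forest_area(self, small_scene):
        drivers, truth, _ = small_scene
        true_forest = drivers.forest_mask & (drivers.artifact_class == CLASS_FOREST)
        n_wilted = truth.labels.sum()
        n_green = (true_forest & ~truth.labels).sum()
        assert n_wilted + n_green == true_forest.sum()

    def test_monotone_prevalence(self, small_config):
        counts = []
        for target in (0.05, 0.108, 0.3):
            cfg = dataclasses.replace(small_config, prevalence_target=target)
            _, truth, _ = generate_scene(cfg)
            counts.append(truth.wilted_count)
        assert counts[0] < counts[1] < counts[2]


class TestNdviSeries:
    def test_noise_free_nonwilted_matches_curve(self, noisefree_scene, noisefree_config):
        drivers, truth, stack = noisefree_scene
        pheno = noisefree_config.phenology
        true_forest = drivers.forest_mask & (drivers.artifact_class == CLASS_FOREST)
        sel = true_forest.ravel() & ~truth.labels.ravel()
        doy = np.where(stack.dates > 365, stack.dates - 365, stack.dates)
        in_2018 = stack.dates <= 365
        expected = pheno(doy[in_2018]).astype(np.float32)
        got = stack.values[sel][:, in_2018]
        np.testing.assert_allclose(got, np.broadcast_to(expected, got.shape), atol=1e-6)

    def test_noise_free_wilted_drop_magnitude_and_timing(self, noisefree_scene, noisefree_config):
        drivers, truth, stack = noisefree_scene
        cfg = noisefree_config
        wilted = truth.labels.ravel()
        summer = (stack.dates >= DOY_MAY1) & (stack.dates <= DOY_SEP30)
        vals = stack.values[wilted][:, summer]
        dts = stack.dates[summer].astype(float)
        diffs = np.diff(vals, axis=1)
        k = np.abs(diffs).argmax(axis=1)
        mags = diffs[np.arange(len(k)), k]
        times = dts[k + 1]
        onsets = truth.onset_day.ravel()[wilted]
        # consecutive-pair drop captures at least half, at most all, of the drop
        assert np.all(mags <= -cfg.wilt_drop / 2)
        # the seasonal curve itself moves a little between observations
        assert np.all(mags >= -cfg.wilt_drop - 0.02)
        gap = cfg.revisit_days + 1
        assert np.all(times >= onsets)
        assert np.all(times <= onsets + cfg.wilt_ramp_days + gap)

    def test_separability_oracle_threshold(self, noisefree_scene, noisefree_config):
        # the generator's own oracle: with no noise, thresholding the max
        # consecutive NDVI drop at wilt_drop/2 reproduces the labels exactly
        drivers, truth, stack = noisefree_scene
        true_forest = drivers.forest_mask & (drivers.artifact_class == CLASS_FOREST)
        sel = true_forest.ravel()
        summer = (stack.dates >= DOY_MAY1) & (stack.dates <= DOY_SEP30)
        diffs = np.diff(stack.values[sel][:, summer], axis=1)
        k = np.abs(diffs).argmax(axis=1)
        mags = diffs[np.arange(len(k)), k]
        pred = mags <= -noisefree_config.wilt_drop / 2
        np.testing.assert_array_equal(pred, truth.labels.ravel()[sel])

    def test_persistence_gap_in_spring_means(self, noisefree_scene, noisefree_config):
        drivers, truth, stack = noisefree_scene
        y2 = (stack.dates >= WINDOW_EARLY_SUMMER_Y2[0]) & (stack.dates <= WINDOW_EARLY_SUMMER_Y2[1])
        y1 = (stack.dates >= WINDOW_EARLY_SUMMER_Y1[0]) & (stack.dates <= WINDOW_EARLY_SUMMER_Y1[1])
        wilted = truth.labels.ravel()
        true_forest = (drivers.forest_mask & (drivers.artifact_class == CLASS_FOREST)).ravel()
        green = true_forest & ~wilted
        gap_y2 = stack.values[green][:, y2].mean() - stack.values[wilted][:, y2].mean()
        gap_y1 = stack.values[green][:, y1].mean() - stack.values[wilted][:, y1].mean()
        assert abs((gap_y2 - gap_y1) - noisefree_config.persistence_delta) < 1e-6

    def test_scene_determinism(self, small_config):
        _, t1, s1 = generate_scene(small_config)
        _, t2, s2 = generate_scene(small_config)
        np.testing.assert_array_equal(t1.labels, t2.labels)
        np.testing.assert_array_equal(s1.values, s2.values)
        np.testing.assert_array_equal(s1.valid, s2.valid)
        np.testing.assert_array_equal(s1.dates, s2.dates)

    def test_values_clipped(self, small_scene):
        _, _, stack = small_scene
        assert stack.values.min() >= -1.0 and stack.values.max() <= 1.0


class TestClimateStatistics:
    def _cubes(self, value_focal, value_base, days=30, shape=(4, 4)):
        focal = np.full((days, *shape), value_focal, float)
        base = np.full((days, *shape), value_base, float)
        months = np.full(days, 8)
        return focal, months, base, months

    def test_identical_cubes_zero_and_hundred(self):
        f, fm, b, bm = self._cubes(20.0, 20.0)
        _, anom_t = compute_climate_statistics(f, fm, b, bm, [8], "temperature")
        np.testing.assert_allclose(anom_t, 0.0)
        _, anom_p = compute_climate_statistics(f, fm, b, bm, [8], "precipitation")
        np.testing.assert_allclose(anom_p, 100.0)

    def test_precipitation_sum_arithmetic(self):
        f, fm, b, bm = self._cubes(2.0, 2.0)
        total, _ = compute_climate_statistics(f, fm, b, bm, [8], "precipitation")
        np.testing.assert_allclose(total, 60.0)

    def test_half_precipitation_is_fifty_percent(self):
        f, fm, b, bm = self._cubes(1.0, 2.0)
        _, anom = compute_climate_statistics(f, fm, b, bm, [8], "precipitation")
        np.testing.assert_allclose(anom, 50.0)

    def test_rejects_empty_period_and_grid_mismatch(self):
        f, fm, b, bm = self._cubes(1.0, 1.0)
        with pytest.raises(ValueError):
            compute_climate_statistics(f, fm, b, bm, [], "precipitation")
        with pytest.raises(ValueError):
            compute_climate_statistics(f, fm, b[:, :2, :2], bm, [8], "temperature")

    def test_canonical_period_count(self):
        from wiltscan.scene import CANONICAL_PERIODS

        assert len(CANONICAL_PERIODS) == 15
        assert all(p == tuple(range(p[0], p[-1] + 1)) for p in CANONICAL_PERIODS)


def test_phenology_curve_bounds():
    p = Phenology()
    days = np.arange(1, 730)
    v = p(days)
    assert np.all((v >= -1) & (v <= 1))
    # summer plateau near summer_ndvi, winter near winter_ndvi
    assert abs(p(200) - p.summer_ndvi) < 0.01
    assert abs(p(20) - p.winter_ndvi) < 0.01
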