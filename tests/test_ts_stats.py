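"""Window statistics, CAT change-point analysis and feature assembly,
checked against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from wiltscan import (
    FEATURE_NAMES,
    assemble_features,
    cat_analysis,
    screen_features,
    window_stats,
)
from wiltscan.scene import DOY_MAY1, DOY_SEP30


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_change_point(dates, values, valid):
    """Exhaustive search over consecutive valid pairs, earliest max |diff|."""
    d = [(t, v) for t, v, ok in zip(dates, values, valid) if ok]
    best = None
    for (t0, v0), (t1, v1) in zip(d[:-1], d[1:]):
        cand = (abs(v1 - v0), t1, v1 - v0, t0)
        if best is None or cand[0] > best[0] + 1e-15:
            best = cand
    return best  # (absmag, time, signed mag, prev time)


def closed_form_ols(x, y):
    """Slope, intercept, two-sided slope p-value and mean |residual|."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    slope = ((x - xb) * (y - yb)).sum() / sxx
    intercept = yb - slope * xb
    resid = y - (slope * x + intercept)
    sse = (resid**2).sum()
    if sse <= 1e-300:
        p = 1.0 if abs(slope) < 1e-300 else 0.0
    else:
        se = np.sqrt(sse / (n - 2) / sxx)
        p = 2 * sps.t.sf(abs(slope / se), n - 2)
    return slope, intercept, p, np.abs(resid).mean()


def random_series(rng, n=30, frac_valid=0.8):
    dates = np.sort(rng.choice(np.arange(DOY_MAY1, DOY_SEP30 + 1), size=n, replace=False))
    values = rng.uniform(-0.2, 0.9, size=n)
    valid = rng.random(n) < frac_valid
    while valid.sum() < 4:
        valid = rng.random(n) < frac_valid
    return dates, values, valid


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

class TestWindowStats:
    def test_small_example(self):
        dates = np.array([130, 140, 150])
        ws = window_stats(dates, np.array([0.2, 0.4, 0.6]), np.ones(3, bool), (121, 181))
        assert (ws.min, ws.max, ws.mean, ws.n_valid) == (0.2, 0.6, pytest.approx(0.4), 3)

    def test_all_invalid_flagged_missing(self):
        dates = np.array([130, 140, 150])
        ws = window_stats(dates, np.array([0.2, 0.4, 0.6]), np.zeros(3, bool), (121, 181))
        assert ws.n_valid == 0
        assert np.isnan(ws.mean) and np.isnan(ws.min) and np.isnan(ws.sd)

    def test_matches_direct_recomputation(self, rng):
        dates = np.arange(121, 121 + 20 * 4, 4)
        values = rng.uniform(0, 1, size=20)
        valid = np.ones(20, bool)
        ws = window_stats(dates, values, valid, (121, 273))
        assert ws.mean == pytest.approx(values.mean(), abs=1e-12)
        assert ws.sd == pytest.approx(values.std(ddof=1), abs=1e-12)

    def test_observations_outside_window_ignored(self, rng):
        dates = np.array([60, 130, 300])
        values = np.array([-0.9, 0.5, 0.9])
        ws = window_stats(dates, values, np.ones(3, bool), (121, 181))
        assert ws.n_valid == 1 and ws.mean == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# CAT analysis
# ---------------------------------------------------------------------------

class TestCatAnalysis:
    def test_constructed_step_series(self):
        dates = np.array([130, 150, 170, 190, 210])
        values = np.array([0.8, 0.8, 0.8, 0.4, 0.4])
        r = cat_analysis(dates, values, np.ones(5, bool))
        assert r.change_time == 190
        assert r.change_magnitude == pytest.approx(-0.4)

    def test_constant_series(self):
        dates = np.arange(130, 230, 10)
        r = cat_analysis(dates, np.full(10, 0.7), np.ones(10, bool))
        assert r.change_magnitude == pytest.approx(0.0)
        assert r.trend_full[0] == pytest.approx(0.0, abs=1e-14)
        assert r.mae == pytest.approx(0.0, abs=1e-14)
        assert r.trend_full_p == pytest.approx(1.0)

    def test_too_few_observations_flagged(self):
        dates = np.array([130, 150, 170])
        r = cat_analysis(dates, np.array([0.1, 0.2, 0.3]), np.ones(3, bool))
        assert np.isnan(r.change_magnitude) and np.isnan(r.mae)
        assert r.n_valid == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracles_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            dates, values, valid = random_series(rng)
            r = cat_analysis(dates, values, valid)
            absmag, t1, mag, _ = brute_force_change_point(dates, values, valid)
            assert r.change_time == t1
            assert r.change_magnitude == pytest.approx(mag, abs=1e-10)
            x, y = dates[valid].astype(float), values[valid]
            slope, intercept, p, mae = closed_form_ols(x, y)
            assert r.trend_full[0] == pytest.approx(slope, abs=1e-10)
            assert r.trend_full[1] == pytest.approx(intercept, abs=1e-8)
            assert r.trend_full_p == pytest.approx(p, abs=1e-10)
            assert r.mae == pytest.approx(mae, abs=1e-10)

    def test_segment_trends_match_ols_oracle(self, rng):
        for _ in range(20):
            dates, values, valid = random_series(rng, n=40)
            r = cat_analysis(dates, values, valid)
            _, t1, _, t0 = brute_force_change_point(dates, values, valid)
            before = valid & (dates <= t0)
            after = valid & (dates >= t1)
            for seg_mask, (slope, intercept) in ((before, r.trend_before), (after, r.trend_after)):
                if seg_mask.sum() >= 3:
                    s, i, _, _ = closed_form_ols(dates[seg_mask], values[seg_mask])
                    assert slope == pytest.approx(s, abs=1e-10)
                else:
                    assert np.isnan(slope)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_change_point_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        dates, values, valid = random_series(rng, n=25, frac_valid=0.7)
        r = cat_analysis(dates, values, valid)
        _, t1, mag, _ = brute_force_change_point(dates, values, valid)
        assert r.change_time == t1
        assert r.change_magnitude == pytest.approx(mag, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invalid_observations_are_inert(self, seed):
        # corrupting values at invalid positions never changes any statistic
        rng = np.random.default_rng(seed)
        dates, values, valid = random_series(rng)
        r1 = cat_analysis(dates, values, valid)
        corrupted = values.copy()
        corrupted[~valid] = rng.uniform(-1, 1, size=(~valid).sum())
        r2 = cat_analysis(dates, corrupted, valid)
        for attr in ("change_time", "change_magnitude", "trend_full_p", "mae"):
            a, b = getattr(r1, attr), getattr(r2, attr)
            assert (np.isnan(a) and np.isnan(b)) or a == b

    def test_wilted_pixels_detected_by_cat(self, noisefree_scene, noisefree_config):
        # links CAT to the generator oracle on noise-free wilted pixels
        _, truth, stack = noisefree_scene
        cfg = noisefree_config
        from wiltscan import cat_analysis_stack

        cat = cat_analysis_stack(stack.dates, stack.values, stack.valid)
        w = truth.labels.ravel()
        mags = cat["change_magnitude"][w]
        times = cat["change_time"][w]
        onsets = truth.onset_day.ravel()[w]
        assert np.all(mags <= -cfg.wilt_drop / 2)
        assert np.all(times >= onsets)
        assert np.all(times <= onsets + cfg.wilt_ramp_days + cfg.revisit_days + 1)


# ---------------------------------------------------------------------------
# feature assembly and screening
# ---------------------------------------------------------------------------

class TestFeatures:
    def test_complete_scene_features_finite(self, noisefree_scene):
        _, _, stack = noisefree_scene
        feats, complete = assemble_features(stack)
        assert feats.shape == (stack.values.shape[0], 10)
        assert complete.all()
        assert np.isfinite(feats).all()

    def test_snowed_in_spring_flags_pixel_incomplete(self, noisefree_scene):
        # persistent snow = no valid spring observations -> excluded from prediction
        from wiltscan.scene import WINDOW_SPRING
        _, _, stack = noisefree_scene
        valid = stack.valid.copy()
        spring = (stack.dates >= WINDOW_SPRING[0]) & (stack.dates <= WINDOW_SPRING[1])
        valid[0, spring] = False
        from wiltscan.scene import NdviStack

        st2 = NdviStack(stack.dates, stack.values, valid, stack.shape)
        feats, complete = assemble_features(st2)
        assert not complete[0]
        assert complete[1:].all()

    def test_feature_order_is_fixed(self):
        assert FEATURE_NAMES == [
            "spring_min", "fall_min", "spring_max", "fall_max", "summer_mean",
            "change_magnitude", "change_time", "summer_trend",
            "summer_trend_significance", "summer_mae",
        ]


class TestScreenFeatures:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=200)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        assert screen_features(t, ["a", "b", "c"]) == ["a", "c"]

    def test_independent_columns_all_retained(self, rng):
        t = pd.DataFrame({f"f{i}": rng.normal(size=1000) for i in range(5)})
        assert screen_features(t, list(t.columns)) == list(t.columns)

    def test_relevance_order_decides_among_correlated(self, rng):
        n = 2000
        a = rng.normal(size=n)
        b = 0.95 * a + np.sqrt(1 - 0.95**2) * rng.normal(size=n)  # r ≈ 0.95
        c = rng.normal(size=n)
        t = pd.DataFrame({"a": a, "b": b, "c": c})
        assert screen_features(t, ["b", "a", "c"]) == ["b", "c"]

    def test_constant_column_dropped_with_warning(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=50), "k": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            assert screen_features(t, ["a", "k"]) == ["a"]
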