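"""Per-pixel NDVI time-series statistics used as classifier features.

Two families of statistics are computed from each pixel's dated NDVI
observations:

* seasonal-window summaries (min, max, mean, sd over valid observations in
  a closed date window) for spring (Mar 1–Apr 30), fall (Oct 1–Nov 30),
  summer (May 1–Sep 30) and the two early-summer windows (May 1–Jun 30 of
  each year);
* a Change–Aftereffect–Trend (CAT) analysis of the summer series: the most
  pronounced change point (the consecutive valid-observation pair with the
  largest absolute NDVI difference), its signed magnitude and timing, OLS
  trends for the full period and for the segments before/after the change
  point, the two-sided significance of the full-period slope, and the mean
  absolute residual around the full-period trend line.

All stack-level functions are fully vectorized over pixels; per-pixel
results are NaN-flagged wherever the minimum data requirements (4 valid
observations for CAT, 3 per trend segment, 1 per window) are not met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scene import (
    NdviStack,
    WINDOW_FALL,
    WINDOW_SPRING,
    WINDOW_SUMMER,
)

FEATURE_NAMES = [
    "spring_min",
    "fall_min",
    "spring_max",
    "fall_max",
    "summer_mean",
    "change_magnitude",
    "change_time",
    "summer_trend",
    "summer_trend_significance",
    "summer_mae",
]

MIN_CAT_OBS = 4
MIN_TREND_OBS = 3


@dataclass
class WindowStats:
    window: str
    min: float
    max: float
    mean: float
    sd: float
    n_valid: int


@dataclass
class CatResult:
    change_time: float
    change_magnitude: float
    trend_full: tuple[float, float]      # (slope, intercept)
    trend_before: tuple[float, float]
    trend_after: tuple[float, float]
    trend_full_p: float
    mae: float
    n_valid: int


def _check_series(dates: np.ndarray, values: np.ndarray, valid: np.ndarray) -> None:
    dates = np.asarray(dates)
    if dates.ndim != 1 or np.any(np.diff(dates) <= 0):
        raise ValueError("dates must be strictly increasing 1-D")
    if np.asarray(values).shape[-1] != dates.size or np.asarray(valid).shape[-1] != dates.size:
        raise ValueError("values/valid must match dates length")


def window_stats(
    dates: np.ndarray, values: np.ndarray, valid: np.ndarray, window: tuple[int, int], name: str = ""
) -> WindowStats:
    """Summary statistics of valid observations in a closed date window."""
    _check_series(dates, values, valid)
    m = np.asarray(valid, bool) & (dates >= window[0]) & (dates <= window[1])
    v = np.asarray(values, float)[m]
    if v.size == 0:
        return WindowStats(name, np.nan, np.nan, np.nan, np.nan, 0)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return WindowStats(name, float(v.min()), float(v.max()), float(v.mean()), sd, int(v.size))


def window_stats_stack(
    stack_dates: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray,
    window: tuple[int, int],
) -> dict[str, np.ndarray]:
    """Vectorized window statistics over a (pixels, T) stack."""
    sel = (stack_dates >= window[0]) & (stack_dates <= window[1])
    m = valid[:, sel]
    v = np.where(m, values[:, sel].astype(float), np.nan)
    n = m.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = {
            "min": np.nanmin(np.where(n[:, None] > 0, v, np.inf), axis=1),
            "max": np.nanmax(np.where(n[:, None] > 0, v, -np.inf), axis=1),
            "mean": np.nanmean(v, axis=1),
            "sd": np.nanstd(v, axis=1, ddof=1),
        }
    empty = n == 0
    for k in out:
        out[k] = np.where(empty, np.nan, out[k])
    out["sd"] = np.where(n == 1, 0.0, out["sd"])
    out["n_valid"] = n
    return out


def _ols_stack(dates: np.ndarray, values: np.ndarray, mask: np.ndarray):
    """Per-row OLS of value on date over masked entries.

    Returns slope, intercept, n, and centered Sxx / SSE for inference.
    Rows with n < 2 or zero date spread get NaN.
    """
    w = mask.astype(float)
    n = w.sum(axis=1)
    x = dates[None, :].astype(float)
    y = np.where(mask, values, 0.0).astype(float)
    sx = (w * x).sum(axis=1)
    sy = y.sum(axis=1)
    sxx = (w * x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        slope = sxy_c / sxx_c
        intercept = (sy - slope * sx) / n
        resid = np.where(mask, values - (slope[:, None] * x + intercept[:, None]), 0.0)
        sse = (resid**2).sum(axis=1)
    bad = (n < 2) | ~np.isfinite(slope)
    slope[bad] = np.nan
    intercept[bad] = np.nan
    return slope, intercept, n, sxx_c, sse, resid


def cat_analysis_stack(
    stack_dates: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray,
    period: tuple[int, int] = WINDOW_SUMMER,
) -> dict[str, np.ndarray]:
    """Vectorized CAT analysis of the summer period over a (pixels, T) stack.

    Change point: among consecutive *valid* observation pairs
    (t_k, t_{k+1}), the pair maximizing |v_{k+1} − v_k| (earliest wins
    ties); signed magnitude v_{k+1} − v_k; timing t_{k+1} (the first date
    the change is visible).  Trends are OLS fits of value on date for the
    full period and for observations at ≤ t_k / ≥ t_{k+1}; the full-period
    slope gets a two-sided t-test p-value and the mean absolute residual.
    """
    sel = (stack_dates >= period[0]) & (stack_dates <= period[1])
    dates = stack_dates[sel].astype(float)
    vals = values[:, sel].astype(float)
    m = valid[:, sel].copy()
    P, T = vals.shape
    n_valid = m.sum(axis=1)
    ok = n_valid >= MIN_CAT_OBS

    # forward-fill the previous valid value/date at each position
    idx = np.where(m, np.arange(T)[None, :], -1)
    prev_idx = np.maximum.accumulate(idx, axis=1)
    # previous valid strictly before position t:
    prev_before = np.concatenate([np.full((P, 1), -1), prev_idx[:, :-1]], axis=1)
    has_pair = m & (prev_before >= 0)
    rows = np.arange(P)[:, None]
    prev_vals = vals[rows, np.maximum(prev_before, 0)]
    diffs = np.where(has_pair, vals - prev_vals, np.nan)
    absd = np.where(has_pair, np.abs(diffs), -np.inf)
    k1 = absd.argmax(axis=1)  # earliest among ties (argmax returns first)
    change_mag = diffs[np.arange(P), k1]
    change_time = dates[k1]
    t_prev = dates[np.maximum(prev_before[np.arange(P), k1], 0)]

    slope_f, icpt_f, n_f, sxx_f, sse_f, resid_f = _ols_stack(dates, vals, m)
    mae = np.where(n_f > 0, np.abs(resid_f).sum(axis=1) / np.maximum(n_f, 1), np.nan)

    # slope significance: t-test with n−2 df; perfect fit → p = 1 if slope 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = sse_f / (n_f - 2)
        se = np.sqrt(s2 / sxx_f)
        tstat = slope_f / se
    p = np.full(P, np.nan)
    fin = np.isfinite(tstat)
    p[fin] = 2.0 * sps.t.sf(np.abs(tstat[fin]), np.maximum(n_f[fin] - 2, 1))
    degenerate = np.isfinite(slope_f) & ~fin
    p[degenerate] = np.where(np.isclose(slope_f[degenerate], 0.0), 1.0, 0.0)

    m_before = m & (dates[None, :] <= t_prev[:, None])
    m_after = m & (dates[None, :] >= change_time[:, None])
    slope_b, icpt_b, n_b, *_ = _ols_stack(dates, vals, m_before)
    slope_a, icpt_a, n_a, *_ = _ols_stack(dates, vals, m_after)
    slope_b[n_b < MIN_TREND_OBS] = np.nan
    icpt_b[n_b < MIN_TREND_OBS] = np.nan
    slope_a[n_a < MIN_TREND_OBS] = np.nan
    icpt_a[n_a < MIN_TREND_OBS] = np.nan

    out = {
        "change_time": change_time,
        "change_magnitude": change_mag,
        "trend_full_slope": slope_f,
        "trend_full_intercept": icpt_f,
        "trend_before_slope": slope_b,
        "trend_before_intercept": icpt_b,
        "trend_after_slope": slope_a,
        "trend_after_intercept": icpt_a,
        "trend_full_p": p,
        "mae": mae,
        "n_valid": n_valid,
    }
    for k, v in out.items():
        if k != "n_valid":
            out[k] = np.where(ok, v, np.nan)
    return out


def cat_analysis(
    dates: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray,
    period: tuple[int, int] = WINDOW_SUMMER,
) -> CatResult:
    """CAT analysis of a single pixel's series (see :func:`cat_analysis_stack`)."""
    _check_series(dates, values, valid)
    r = cat_analysis_stack(
        np.asarray(dates), np.asarray(values, float)[None, :], np.asarray(valid, bool)[None, :], period
    )
    return CatResult(
        change_time=float(r["change_time"][0]),
        change_magnitude=float(r["change_magnitude"][0]),
        trend_full=(float(r["trend_full_slope"][0]), float(r["trend_full_intercept"][0])),
        trend_before=(float(r["trend_before_slope"][0]), float(r["trend_before_intercept"][0])),
        trend_after=(float(r["trend_after_slope"][0]), float(r["trend_after_intercept"][0])),
        trend_full_p=float(r["trend_full_p"][0]),
        mae=float(r["mae"][0]),
        n_valid=int(r["n_valid"][0]),
    )


def assemble_features(stack: NdviStack) -> tuple[np.ndarray, np.ndarray]:
    """The 10 classifier features for every pixel of an NDVI stack.

    Returns ``(features, complete)`` where features is (n_pixels, 10) in
    :data:`FEATURE_NAMES` order and ``complete`` marks pixels whose every
    feature is defined (e.g. snow-free spring coverage); incomplete pixels
    are excluded from prediction downstream.
    """
    spring = window_stats_stack(stack.dates, stack.values, stack.valid, WINDOW_SPRING)
    fall = window_stats_stack(stack.dates, stack.values, stack.valid, WINDOW_FALL)
    summer = window_stats_stack(stack.dates, stack.values, stack.valid, WINDOW_SUMMER)
    cat = cat_analysis_stack(stack.dates, stack.values, stack.valid)
    feats = np.column_stack(
        [
            spring["min"],
            fall["min"],
            spring["max"],
            fall["max"],
            summer["mean"],
            cat["change_magnitude"],
            cat["change_time"],
            cat["trend_full_slope"],
            cat["trend_full_p"],
            cat["mae"],
        ]
    )
    complete = np.isfinite(feats).all(axis=1)
    return feats, complete


def screen_features(
    table: pd.DataFrame, relevance_order: list[str], r_max: float = 0.75
) -> list[str]:
    """Greedy correlation screening: keep candidates in relevance order
    whose absolute Pearson correlation with every already-retained feature
    is ≤ r_max.  Constant columns are dropped with a warning (undefined r).
    """
    if len(relevance_order) < 2:
        raise ValueError("need at least 2 candidate features")
    retained: list[str] = []
    for name in relevance_order:
        col = table[name].to_numpy(float)
        if np.nanstd(col) == 0:
            warnings.warn(f"feature {name!r} is constant; correlation undefined, dropped")
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(col, table[kept].to_numpy(float))[0, 1]
            if abs(r) > r_max:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained
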