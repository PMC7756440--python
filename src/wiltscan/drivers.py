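"""Environment–wilting relationships via balanced samples and additive models.

Wilting–driver relationships are quantified at several spatial scales by
(1) drawing class-balanced samples of mapped pixels (fine scale) or of
coarse aggregation cells re-weighted so total presence weight equals total
absence weight, and (2) fitting smooth additive logistic models
(binomial GAMs) per driver (univariate) and for the full driver set
(multivariate).  Calibration strength is reported as explained deviance
(D_null − D_model)/D_null, and response curves come from the median and
2.5/97.5% pointwise quantiles of an ensemble of refits on re-drawn samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.gam.api import BSplines

from .classifier import PredictionRaster

DEFAULT_DF = 6
SOIL_DF = 3  # crude ordinal soil classes: basis dimension capped at 3

SOIL_CLASS_DRIVERS = ("rooting_depth", "hydraulic_conductivity")


@dataclass
class BalancedSample:
    """Sampled units with presence/absence weights per unit."""

    data: pd.DataFrame          # driver columns + presence_weight/absence_weight
    scale: str                  # regional | intermediate | broad

    def __post_init__(self) -> None:
        wp = self.data["presence_weight"].sum()
        wa = self.data["absence_weight"].sum()
        if not np.isclose(wp, wa, rtol=0, atol=1e-9 * max(wp, 1.0)):
            raise ValueError("sample is not balanced")
        if (self.data[["presence_weight", "absence_weight"]].to_numpy() < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def drivers(self) -> list[str]:
        return [c for c in self.data.columns if not c.endswith("_weight")]


def sample_regional(
    pred: PredictionRaster,
    driver_layers: dict[str, np.ndarray],
    n_each: int = 5000,
    seed: int | None = None,
) -> BalancedSample:
    """Balanced fine-scale sample: n_each predicted-presence pixels and
    n_each predicted-absence pixels, unit weights, drivers at pixel scale."""
    rng = np.random.default_rng(seed)
    cls = pred.classes.ravel()
    rows = []
    for code, is_presence in ((1, True), (0, False)):
        pool = np.flatnonzero(cls == code)
        if pool.size == 0:
            raise ValueError(f"no pixels in predicted class {code}")
        take = n_each
        if pool.size < n_each:
            warnings.warn(f"class {code} has only {pool.size} pixels; sampling all")
            take = pool.size
        pick = rng.choice(pool, size=take, replace=False)
        rec = {name: layer.ravel()[pick] for name, layer in driver_layers.items()}
        rec["presence_weight"] = np.where(is_presence, 1.0, 0.0)
        rec["absence_weight"] = np.where(is_presence, 0.0, 1.0)
        rows.append(pd.DataFrame(rec))
    data = pd.concat(rows, ignore_index=True)
    # exact balance even when one class was exhausted
    wp, wa = data["presence_weight"].sum(), data["absence_weight"].sum()
    if wp != wa and wp > 0:
        data["presence_weight"] *= wa / wp
    return BalancedSample(data, scale="regional")


def sample_coarse(
    fraction: np.ndarray,
    forest_counts: np.ndarray,
    driver_layers: dict[str, np.ndarray],
    n_cells: int = 10_000,
    seed: int | None = None,
    scale: str = "broad",
) -> BalancedSample:
    """Balanced coarse-cell sample.

    Cells with any missing driver or fraction are excluded before
    sampling.  For each sampled cell k with p_k presence and a_k absence
    pixels, presence weight = c·p_k and absence weight = a_k, with
    c = Σa_k/Σp_k over the sample, so total presence weight equals total
    absence weight (non-integer weights allowed).
    """
    rng = np.random.default_rng(seed)
    ok = np.isfinite(fraction) & (forest_counts > 0)
    for layer in driver_layers.values():
        ok &= np.isfinite(layer)
    pool = np.flatnonzero(ok.ravel())
    if pool.size == 0:
        raise ValueError("no cells with complete data coverage")
    take = min(n_cells, pool.size)
    if take < n_cells:
        warnings.warn(f"only {pool.size} complete cells; sampling all")
    pick = rng.choice(pool, size=take, replace=False)
    p_k = (fraction.ravel()[pick] * forest_counts.ravel()[pick]).astype(float)
    a_k = forest_counts.ravel()[pick] - p_k
    if p_k.sum() == 0:
        raise ValueError("sample contains no presence pixels")
    c = a_k.sum() / p_k.sum()
    rec = {name: layer.ravel()[pick] for name, layer in driver_layers.items()}
    rec["presence_weight"] = c * p_k
    rec["absence_weight"] = a_k
    return BalancedSample(pd.DataFrame(rec), scale=scale)


@dataclass
class GamFitSummary:
    model_id: str
    explained_deviance: float
    deviance: float
    null_deviance: float
    drivers: list[str]
    basis_df: list[int]
    curve_grid: np.ndarray | None = None       # univariate only
    curve_values: np.ndarray | None = None     # fitted probability on grid
    edf: np.ndarray | None = None


class DriverGAM(BaseEstimator):
    """Additive logistic (or Gaussian) model with one smooth term per driver.

    Smooth terms are B-spline regression bases (cubic, basis dimension
    ``df``; soil-class drivers are capped at basis dimension 3 with
    quadratic splines) fitted by IRLS as a generalized linear model on the
    concatenated basis.  The binomial response is the weighted presence
    fraction with total weight as binomial trials (non-integer weights
    supported); a Gaussian family serves continuous responses.
    """

    def __init__(
        self,
        drivers: Sequence[str] = (),
        soil_class_drivers: Sequence[str] = SOIL_CLASS_DRIVERS,
        df: int = DEFAULT_DF,
        family: str = "binomial",
    ):
        self.drivers = drivers
        self.soil_class_drivers = soil_class_drivers
        self.df = df
        self.family = family

    def _basis(self, X: np.ndarray):
        dfs, degs = [], []
        for name in self.drivers:
            if name in self.soil_class_drivers:
                dfs.append(SOIL_DF)
                degs.append(2)
            else:
                dfs.append(self.df)
                degs.append(3)
        return BSplines(X, df=dfs, degree=degs, include_intercept=False), dfs

    def fit(self, sample: BalancedSample | pd.DataFrame, response: np.ndarray | None = None):
        """Fit on a BalancedSample (binomial) or on (DataFrame, response) (gaussian)."""
        if not self.drivers:
            raise ValueError("need at least one driver")
        if isinstance(sample, BalancedSample):
            data = sample.data
            s = data["presence_weight"].to_numpy(float)
            f = data["absence_weight"].to_numpy(float)
            w = s + f
            keep = w > 0
            endog = s[keep] / w[keep]
            var_weights = w[keep]
            X = data.loc[keep, list(self.drivers)].to_numpy(float)
        else:
            if response is None:
                raise ValueError("continuous fits need an explicit response")
            X = np.asarray(sample[list(self.drivers)], dtype=float)
            endog = np.asarray(response, float)
            keep = np.isfinite(endog) & np.isfinite(X).all(axis=1)
            X, endog = X[keep], endog[keep]
            var_weights = np.ones(endog.size)
        if not np.isfinite(X).all():
            raise ValueError("non-finite predictor values")
        fam = sm.families.Binomial() if self.family == "binomial" else sm.families.Gaussian()
        smoother, dfs = self._basis(X)
        design = np.column_stack([np.ones(endog.size), smoother.basis])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # perfect-separation style warnings
            self.results_ = sm.GLM(endog, design, family=fam, var_weights=var_weights).fit()
        self.smoother_ = smoother
        self.basis_df_ = dfs
        self.deviance_ = float(self.results_.deviance)
        null = sm.GLM(endog, np.ones((endog.size, 1)), family=fam, var_weights=var_weights).fit()
        self.null_deviance_ = float(null.deviance)
        self.explained_deviance_ = (
            1.0 - self.deviance_ / self.null_deviance_ if self.null_deviance_ > 0 else 0.0
        )
        self.driver_ranges_ = np.column_stack([X.min(axis=0), X.max(axis=0)])
        self.n_obs_ = int(endog.size)
        return self

    def predict_curve(self, grid: np.ndarray) -> np.ndarray:
        """Fitted response on a grid (univariate models only)."""
        check_is_fitted(self, "results_")
        if len(self.drivers) != 1:
            raise ValueError("response curves are defined for univariate models")
        grid = np.asarray(grid, float)
        lo, hi = self.driver_ranges_[0]
        clipped = np.clip(grid, lo, hi)  # B-spline basis undefined outside data span
        basis = self.smoother_.transform(clipped[:, None])
        design = np.column_stack([np.ones(grid.size), basis])
        return np.asarray(self.results_.predict(design))

    def summary(self, model_id: str | None = None) -> GamFitSummary:
        check_is_fitted(self, "results_")
        mid = model_id or (
            f"univariate:{self.drivers[0]}" if len(self.drivers) == 1 else "multivariate"
        )
        return GamFitSummary(
            model_id=mid,
            explained_deviance=self.explained_deviance_,
            deviance=self.deviance_,
            null_deviance=self.null_deviance_,
            drivers=list(self.drivers),
            basis_df=list(self.basis_df_),
        )


def fit_driver_model(
    sample: BalancedSample,
    drivers: Sequence[str],
    soil_class_drivers: Sequence[str] = SOIL_CLASS_DRIVERS,
    family: str = "binomial",
    response: np.ndarray | None = None,
    **kwargs,
) -> GamFitSummary:
    """Convenience wrapper: fit a DriverGAM and return its summary."""
    gam = DriverGAM(
        drivers=list(drivers), soil_class_drivers=soil_class_drivers, family=family, **kwargs
    ).fit(sample, response)
    s = gam.summary()
    if len(drivers) == 1:
        lo, hi = gam.driver_ranges_[0]
        grid = np.linspace(lo, hi, 50)
        s.curve_grid = grid
        s.curve_values = gam.predict_curve(grid)
    return s


def explained_deviance_table(
    sample: BalancedSample,
    drivers: Sequence[str],
    soil_class_drivers: Sequence[str] = SOIL_CLASS_DRIVERS,
    family: str = "binomial",
    response: np.ndarray | None = None,
) -> pd.DataFrame:
    """Univariate explained deviance per driver plus the multivariate model."""
    rows = []
    for d in drivers:
        s = fit_driver_model(sample, [d], soil_class_drivers, family, response)
        rows.append({"model": s.model_id, "explained_deviance": s.explained_deviance})
    s = fit_driver_model(sample, list(drivers), soil_class_drivers, family, response)
    rows.append({"model": s.model_id, "explained_deviance": s.explained_deviance})
    return pd.DataFrame(rows)


@dataclass
class ResponseCurveEnsemble:
    driver: str
    grid: np.ndarray
    median: np.ndarray
    lower: np.ndarray    # pointwise 2.5%
    upper: np.ndarray    # pointwise 97.5%
    curves: np.ndarray   # (n_refits, grid)
    seeds: list[int] = field(default_factory=list)


def response_curves(
    sample_fn: Callable[[int], BalancedSample],
    driver: str,
    n_refits: int = 100,
    master_seed: int = 0,
    grid_size: int = 50,
    soil_class_drivers: Sequence[str] = SOIL_CLASS_DRIVERS,
    family: str = "binomial",
    response_fn: Callable[[BalancedSample], np.ndarray] | None = None,
) -> ResponseCurveEnsemble:
    """Median and 95% pointwise interval of fitted curves over re-drawn samples.

    ``sample_fn(seed)`` must return a fresh BalancedSample; each refit uses
    a child seed of ``master_seed``.  Curves are evaluated on a fixed grid
    spanning the 1st–99th percentile of the driver in the first sample.
    """
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(master_seed).spawn(n_refits)]
    grid = None
    curves = []
    used = []
    for sd in seeds:
        try:
            sample = sample_fn(sd)
            if grid is None:
                x = sample.data[driver].to_numpy(float)
                grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), grid_size)
            gam = DriverGAM([driver], soil_class_drivers, family=family)
            resp = response_fn(sample) if response_fn is not None else None
            gam.fit(sample if resp is None else sample.data, resp)
            curves.append(gam.predict_curve(grid))
            used.append(sd)
        except Exception as exc:
            warnings.warn(f"refit with seed {sd} failed: {exc}")
    if len(curves) < 2:
        raise RuntimeError("fewer than 2 successful refits")
    arr = np.vstack(curves)
    return ResponseCurveEnsemble(
        driver=driver,
        grid=grid,
        median=np.median(arr, axis=0),
        lower=np.percentile(arr, 2.5, axis=0),
        upper=np.percentile(arr, 97.5, axis=0),
        curves=arr,
        seeds=used,
    )
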