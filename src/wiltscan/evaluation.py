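"""End-to-end evaluation experiments on fully known synthetic scenes.

Each function runs one self-contained recovery experiment — map-and-estimate
on a fresh scene, driver-importance ranking, following-spring delta
recovery — and returns plain numbers, so the same code backs both the test
suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import (
    NOT_PREDICTED,
    PredictionRaster,
    WiltingClassifier,
    build_training_set,
    predict_wilting,
    rasterize_labels,
)
from .drivers import (
    fit_driver_model,
    response_curves,
    sample_regional,
)
from .persistence import cell_persistence, persistence_driver_models
from .scene import (
    CLASS_FOREST,
    SceneConfig,
    WINDOW_EARLY_SUMMER_Y1,
    WINDOW_EARLY_SUMMER_Y2,
    generate_scene,
    sample_label_polygons,
)
from .ts_stats import assemble_features, window_stats_stack
from .validation import draw_test_sample, estimate_area, post_stratified_accuracy


@dataclass
class EndToEndResult:
    heldout_accuracy: float
    overall_accuracy: float
    ppv: float
    npv: float
    predicted_prevalence: float
    true_prevalence: float
    est_area_km2: float
    est_area_se_km2: float
    true_area_km2: float
    total_area_km2: float
    covered: bool


def run_end_to_end(
    seed: int,
    config: SceneConfig | None = None,
    n_polygons: int = 30,
    n_per_stratum: int = 500,
    n_trees: int = 200,
) -> EndToEndResult:
    """One full scene → features → train (30 polygons) → predict → validate run.

    The held-out accuracy is population accuracy over predicted forest
    pixels outside the training polygons, scored on generator truth; the
    area estimate targets the truth-wilted area within the prediction frame.
    """
    cfg = (config or SceneConfig()).with_seed(seed)
    drivers, truth, stack = generate_scene(cfg)
    feats, complete = assemble_features(stack)
    n_art = max(2, n_polygons // 10)
    n_pres = (n_polygons - n_art) // 2
    n_abs = n_polygons - n_art - n_pres
    polys = sample_label_polygons(truth, n_pres, n_abs, n_art, seed=seed + 1)
    labeled, _ = rasterize_labels(polys, truth.labels.shape, cfg.pixel_size)
    X, y, train_idx = build_training_set(labeled, feats, complete, truth.labels.shape)
    model = WiltingClassifier(n_trees=n_trees, random_state=seed + 2).fit(X, y)
    pred = predict_wilting(model, feats, complete, drivers.forest_mask, cfg.pixel_size)

    pm = pred.predicted_mask.ravel()
    heldout = pm.copy()
    heldout[train_idx] = False
    lab = truth.labels.ravel()
    heldout_acc = float((pred.presence_mask.ravel()[heldout] == lab[heldout]).mean())

    matrix, design = draw_test_sample(pred, truth, n_per_stratum, seed=seed + 3)
    acc = post_stratified_accuracy(matrix, design)
    total_km2 = pm.sum() * cfg.pixel_size**2 / 1e6
    area = estimate_area(matrix, design, total_km2)
    true_km2 = lab[pm].sum() * cfg.pixel_size**2 / 1e6
    lo, hi = area.ci(0)
    return EndToEndResult(
        heldout_accuracy=heldout_acc,
        overall_accuracy=float(acc.overall_accuracy),
        ppv=float(acc.users_accuracy[0]),
        npv=float(acc.users_accuracy[1]),
        predicted_prevalence=float(pred.presence_mask.sum() / pm.sum()),
        true_prevalence=float(lab[pm].mean()),
        est_area_km2=float(area.areas[0]),
        est_area_se_km2=float(area.areas_se[0]),
        true_area_km2=true_km2,
        total_area_km2=float(total_km2),
        covered=bool(lo <= true_km2 <= hi),
    )


def _truth_prediction(truth, drivers, pixel_size: float) -> PredictionRaster:
    """A prediction raster that equals generator truth on true forest."""
    frame = drivers.forest_mask & (drivers.artifact_class == CLASS_FOREST)
    classes = np.where(frame, truth.labels.astype(np.uint8), NOT_PREDICTED).astype(np.uint8)
    return PredictionRaster(classes, np.full(classes.shape, np.nan), frame, pixel_size)


RANK_EFFECTS = {
    "aug_tmax_anom": (1.5, 0.0),    # strong
    "aug_precip_anom": (-0.5, 0.0),  # weak
    # nuisance carries no effect: the null driver
}


def driver_rank_experiment(
    n_refits: int = 100,
    seed: int = 0,
    grid: int = 250,
    n_each: int = 5000,
) -> dict:
    """Strong/weak/null driver-recovery on one known scene.

    Each refit re-draws the balanced regional sample and fits the three
    univariate binomial additive models; a win = explained deviance ordered
    strong > weak > null.
    """
    cfg = SceneConfig(
        grid_rows=grid, grid_cols=grid, seed=seed,
        driver_effects=dict(RANK_EFFECTS, veg_height=(0.0, -0.8)),
    )
    drivers, truth, _ = generate_scene(cfg)
    pred = _truth_prediction(truth, drivers, cfg.pixel_size)
    layers = {n: drivers[n] for n in ("aug_tmax_anom", "aug_precip_anom", "nuisance", "veg_height")}
    rng = np.random.SeedSequence(seed + 1).spawn(n_refits)
    wins = 0
    for ss in rng:
        s = sample_regional(pred, layers, n_each=n_each, seed=int(ss.generate_state(1)[0] % 2**31))
        dev = {
            name: fit_driver_model(s, [name]).explained_deviance
            for name in ("aug_tmax_anom", "aug_precip_anom", "nuisance")
        }
        wins += dev["aug_tmax_anom"] > dev["aug_precip_anom"] > dev["nuisance"]

    def sample_fn(sd):
        return sample_regional(pred, layers, n_each=n_each, seed=sd)

    mono = response_curves(sample_fn, "aug_tmax_anom", n_refits=min(n_refits, 30), master_seed=seed + 7)
    g = mono.grid
    central = (g >= np.quantile(g, 0.1)) & (g <= np.quantile(g, 0.9))
    monotone_ok = bool(np.all(np.diff(mono.median[central]) > -1e-6))

    uni = response_curves(sample_fn, "veg_height", n_refits=min(n_refits, 30), master_seed=seed + 8)
    peak = uni.grid[int(np.argmax(uni.median))]
    lo, hi = np.quantile(uni.grid, [1 / 3, 2 / 3])
    unimodal_ok = bool(lo <= peak <= hi)
    return {"wins": int(wins), "n_refits": n_refits,
            "monotone_ok": monotone_ok, "unimodal_ok": unimodal_ok}


def persistence_recovery_experiment(
    n_scenes: int = 20,
    seed: int = 0,
    grid: int = 150,
    coarse_factor: int = 30,
) -> dict:
    """Mean within-cell spring-delta across seeded scenes vs the configured truth."""
    means = []
    for k in range(n_scenes):
        cfg = SceneConfig(grid_rows=grid, grid_cols=grid, coarse_factor=coarse_factor,
                          seed=seed + 1000 * (k + 1))
        drivers, truth, stack = generate_scene(cfg)
        shape = truth.labels.shape
        s18 = window_stats_stack(stack.dates, stack.values, stack.valid,
                                 WINDOW_EARLY_SUMMER_Y1)["mean"].reshape(shape)
        s19 = window_stats_stack(stack.dates, stack.values, stack.valid,
                                 WINDOW_EARLY_SUMMER_Y2)["mean"].reshape(shape)
        pred = _truth_prediction(truth, drivers, cfg.pixel_size)
        cells = cell_persistence(pred, s18, s19, coarse_factor)
        means.append(float(cells["delta"].dropna().mean()))
    means = np.array(means)
    return {
        "mean_delta": float(means.mean()),
        "mc_se": float(means.std(ddof=1) / np.sqrt(n_scenes)),
        "n_scenes": n_scenes,
        "target": SceneConfig().persistence_delta,
    }


def magnitude_rank_experiment(n_refits: int = 100, seed: int = 0, n_side: int = 70) -> dict:
    """Cells constructed with delta ∝ |change magnitude|: how often does the
    magnitude predictor rank first by univariate explained deviance?"""
    wins = 0
    for k in range(n_refits):
        rng = np.random.default_rng(seed + k)
        mag = -np.abs(rng.normal(0.3, 0.08, size=(n_side, n_side)))
        time = rng.uniform(213, 258, size=(n_side, n_side))
        noise = rng.normal(size=(n_side, n_side))
        delta = 0.1 * np.abs(mag) + rng.normal(0, 0.01, size=(n_side, n_side))
        cells = pd.DataFrame({
            "cell_row": np.repeat(np.arange(n_side), n_side),
            "cell_col": np.tile(np.arange(n_side), n_side),
            "delta": delta.ravel(),
        })
        layers = {"mean_change_magnitude": mag, "mean_change_time": time, "nuisance": noise}
        tab = persistence_driver_models(cells, layers)
        uni = tab[tab["model"] != "multivariate"].set_index("model")["explained_deviance"]
        wins += uni.idxmax() == "univariate:mean_change_magnitude"
    return {"wins": int(wins), "n_refits": n_refits}
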