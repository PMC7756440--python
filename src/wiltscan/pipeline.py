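"""File-based pipeline stages with run manifests.

Stage order: simulate → features → train → predict → validate → drivers →
persistence.  Each stage reads the artifacts of its upstream stages from
the run directory, writes its own artifacts, and records a manifest
(config hash, seed, package version, input checksums) so any run can be
replayed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    PredictionRaster,
    WiltingClassifier,
    aggregate_fraction,
    build_training_set,
    predict_wilting,
    rasterize_labels,
)
from .drivers import explained_deviance_table, sample_coarse, sample_regional
from .persistence import aggregate_cat_to_cells, cell_persistence, persistence_driver_models
from .rasters import (
    read_byte_raster,
    read_dates_csv,
    read_raster,
    write_byte_raster,
    write_dates_csv,
    write_raster,
)
from .scene import (
    SceneConfig,
    WINDOW_EARLY_SUMMER_Y1,
    WINDOW_EARLY_SUMMER_Y2,
    generate_scene,
    sample_label_polygons,
)
from .ts_stats import FEATURE_NAMES, assemble_features, cat_analysis_stack, window_stats_stack
from .validation import draw_test_sample, estimate_area, post_stratified_accuracy

STAGES = ["simulate", "features", "train", "predict", "validate", "drivers", "persistence"]

#: artifacts each stage consumes, mapped to the stage that produces them
_REQUIRES = {
    "features": {"ndvi_values.tif": "simulate"},
    "train": {"features.tif": "features", "labels.geojson": "simulate"},
    "predict": {"features.tif": "features", "model.joblib": "train"},
    "validate": {"prediction.tif": "predict", "truth_labels.tif": "simulate"},
    "drivers": {"prediction.tif": "predict"},
    "persistence": {"prediction.tif": "predict", "spring_y1.tif": "features"},
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    d["phenology"] = dataclasses.asdict(config.phenology)
    d["driver_effects"] = {k: list(v) for k, v in config.driver_effects.items()}
    return d


def write_manifest(outdir: Path, stage: str, config: SceneConfig, inputs: list[Path]) -> None:
    cfg = _config_dict(config)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "package_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": {p.name: _sha256(p) for p in inputs if p.exists()},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def _require(outdir: Path, stage: str) -> None:
    for fname, producer in _REQUIRES.get(stage, {}).items():
        if not (outdir / fname).exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {fname!r}; run the {producer!r} stage first"
            )


def save_config(config: SceneConfig, path: Path) -> None:
    """Plain-text key=value config file (nested keys dotted)."""
    lines = []

    def emit(prefix: str, d: dict) -> None:
        for k, v in d.items():
            if isinstance(v, dict):
                emit(f"{prefix}{k}.", v)
            else:
                lines.append(f"{prefix}{k} = {json.dumps(v)}")

    emit("", _config_dict(config))
    path.write_text("\n".join(lines) + "\n")


def load_config(path: Path) -> SceneConfig:
    flat: dict[str, object] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        flat[key.strip()] = json.loads(val.strip())
    from .scene import Phenology

    pheno = Phenology(**{k.split(".", 1)[1]: v for k, v in flat.items() if k.startswith("phenology.")})
    effects = {}
    for k, v in flat.items():
        if k.startswith("driver_effects."):
            effects[k.split(".", 1)[1]] = tuple(v)
    plain = {
        k: v
        for k, v in flat.items()
        if "." not in k and k not in ("phenology", "driver_effects")
    }
    if "wilt_onset_window" in plain:
        plain["wilt_onset_window"] = tuple(plain["wilt_onset_window"])
    return SceneConfig(phenology=pheno, driver_effects=effects, **plain)


def stage_simulate(config: SceneConfig, outdir: Path, n_polygons: int = 30) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    drivers, truth, stack = generate_scene(config)
    for name, layer in drivers.layers.items():
        write_raster(outdir / f"driver_{name}.tif", layer)
    write_byte_raster(outdir / "forest_mask.tif", drivers.forest_mask)
    write_byte_raster(outdir / "artifact_class.tif", drivers.artifact_class)
    write_raster(outdir / "truth_probability.tif", truth.probability)
    write_byte_raster(outdir / "truth_labels.tif", truth.labels)
    write_raster(outdir / "truth_onset.tif", truth.onset_day)
    nt = stack.dates.size
    write_raster(outdir / "ndvi_values.tif", stack.values.T.reshape(nt, *truth.labels.shape))
    write_byte_raster(outdir / "ndvi_valid.tif", stack.valid.T.reshape(nt, *truth.labels.shape))
    write_dates_csv(outdir / "dates.csv", stack.dates)
    n_art = max(2, n_polygons // 10)
    n_pres = (n_polygons - n_art) // 2
    n_abs = n_polygons - n_art - n_pres
    polys = sample_label_polygons(truth, n_pres, n_abs, n_art, seed=config.seed + 1)
    features = []
    for p in polys:
        features.append(
            {
                "type": "Feature",
                "properties": {"label": p.label, "source": p.source},
                "geometry": json.loads(json.dumps(p.geometry.__geo_interface__)),
            }
        )
    (outdir / "labels.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    save_config(config, outdir / "scene.cfg")
    write_manifest(outdir, "simulate", config, [])


def _load_stack(outdir: Path):
    from .scene import NdviStack

    cube = read_raster(outdir / "ndvi_values.tif")
    vcube = read_byte_raster(outdir / "ndvi_valid.tif").astype(bool)
    mask = read_byte_raster(outdir / "forest_mask.tif").astype(bool)
    values = cube.reshape(cube.shape[0], -1).T
    valid = vcube.reshape(vcube.shape[0], -1).T
    return NdviStack(read_dates_csv(outdir / "dates.csv"), values, valid, mask.shape), mask


def stage_features(config: SceneConfig, outdir: Path) -> None:
    _require(outdir, "features")
    stack, mask = _load_stack(outdir)
    feats, complete = assemble_features(stack)
    bands = feats.T.reshape(len(FEATURE_NAMES), *mask.shape)
    write_raster(outdir / "features.tif", bands)
    pd.DataFrame({"band": range(1, 11), "name": FEATURE_NAMES}).to_csv(
        outdir / "features_bands.csv", index=False
    )
    write_byte_raster(outdir / "features_complete.tif", complete.reshape(mask.shape))
    for tag, window in (("spring_y1", WINDOW_EARLY_SUMMER_Y1), ("spring_y2", WINDOW_EARLY_SUMMER_Y2)):
        ws = window_stats_stack(stack.dates, stack.values, stack.valid, window)
        write_raster(outdir / f"{tag}.tif", ws["mean"].reshape(mask.shape))
    cat = cat_analysis_stack(stack.dates, stack.values, stack.valid)
    write_raster(outdir / "cat_change_time.tif", cat["change_time"].reshape(mask.shape))
    write_raster(outdir / "cat_change_magnitude.tif", cat["change_magnitude"].reshape(mask.shape))
    write_manifest(outdir, "features", config, [outdir / "ndvi_values.tif", outdir / "dates.csv"])


def load_label_polygons(path: Path) -> list:
    from shapely.geometry import shape as shp_shape

    from .scene import LabelPolygon

    gj = json.loads(path.read_text())
    return [
        LabelPolygon(shp_shape(f["geometry"]), f["properties"]["label"], f["properties"].get("source", ""))
        for f in gj["features"]
    ]


def _load_features(outdir: Path):
    bands = read_raster(outdir / "features.tif")
    feats = bands.reshape(len(FEATURE_NAMES), -1).T.astype(float)
    complete = read_byte_raster(outdir / "features_complete.tif").astype(bool).ravel()
    return feats, complete


def stage_train(config: SceneConfig, outdir: Path, n_trees: int = 500) -> None:
    _require(outdir, "train")
    feats, complete = _load_features(outdir)
    mask = read_byte_raster(outdir / "forest_mask.tif").astype(bool)
    polys = load_label_polygons(outdir / "labels.geojson")
    labeled, n_conflicts = rasterize_labels(polys, mask.shape, config.pixel_size)
    if n_conflicts:
        warnings.warn(f"{n_conflicts} label conflicts resolved by priority")
    X, y, flat = build_training_set(labeled, feats, complete, mask.shape)
    model = WiltingClassifier(n_trees=n_trees, random_state=config.seed + 2).fit(X, y)
    joblib.dump({"model": model, "feature_names": FEATURE_NAMES, "train_index": flat}, outdir / "model.joblib")
    write_manifest(outdir, "train", config, [outdir / "features.tif", outdir / "labels.geojson"])


def stage_predict(config: SceneConfig, outdir: Path) -> None:
    _require(outdir, "predict")
    feats, complete = _load_features(outdir)
    mask = read_byte_raster(outdir / "forest_mask.tif").astype(bool)
    model = joblib.load(outdir / "model.joblib")["model"]
    pred = predict_wilting(model, feats, complete, mask, config.pixel_size)
    write_byte_raster(outdir / "prediction.tif", pred.classes)
    write_raster(outdir / "vote_fraction.tif", pred.vote_fraction)
    frac = aggregate_fraction(pred, config.coarse_factor)
    write_raster(outdir / "fraction_coarse.tif", frac)
    write_manifest(outdir, "predict", config, [outdir / "features.tif", outdir / "model.joblib"])


def _load_prediction(config: SceneConfig, outdir: Path) -> PredictionRaster:
    classes = read_byte_raster(outdir / "prediction.tif")
    votes = read_raster(outdir / "vote_fraction.tif")
    mask = read_byte_raster(outdir / "forest_mask.tif").astype(bool)
    return PredictionRaster(classes, votes, mask, config.pixel_size)


def stage_validate(config: SceneConfig, outdir: Path, n_per_stratum: int = 3000) -> None:
    _require(outdir, "validate")
    pred = _load_prediction(config, outdir)
    truth_labels = read_byte_raster(outdir / "truth_labels.tif").astype(bool)

    from .scene import SceneTruth

    truth = SceneTruth(
        probability=read_raster(outdir / "truth_probability.tif"),
        labels=truth_labels,
        onset_day=read_raster(outdir / "truth_onset.tif"),
        artifact_class=read_byte_raster(outdir / "artifact_class.tif"),
        forest_mask=pred.forest_mask,
        pixel_size=config.pixel_size,
    )
    matrix, design = draw_test_sample(pred, truth, n_per_stratum, seed=config.seed + 3)
    total_km2 = pred.predicted_mask.sum() * config.pixel_size**2 / 1e6
    acc = post_stratified_accuracy(matrix, design)
    area = estimate_area(matrix, design, total_km2)
    pd.DataFrame(matrix, index=["pred_presence", "pred_absence"], columns=["ref_presence", "ref_absence"]).to_csv(
        outdir / "error_matrix.csv"
    )
    report = pd.DataFrame(
        {
            "quantity": [
                "overall_accuracy",
                "positive_predictive_value",
                "negative_predictive_value",
                "producers_accuracy_presence",
                "wilted_proportion",
                "wilted_area_km2",
            ],
            "estimate": [
                acc.overall_accuracy,
                acc.users_accuracy[0],
                acc.users_accuracy[1],
                acc.producers_accuracy[0],
                area.proportions[0],
                area.areas[0],
            ],
            "se": [
                acc.overall_accuracy_se,
                acc.users_accuracy_se[0],
                acc.users_accuracy_se[1],
                acc.producers_accuracy_se[0],
                area.proportions_se[0],
                area.areas_se[0],
            ],
        }
    )
    report["ci_lo"] = report["estimate"] - 1.959963984540054 * report["se"]
    report["ci_hi"] = report["estimate"] + 1.959963984540054 * report["se"]
    report.to_csv(outdir / "accuracy_report.csv", index=False)
    write_manifest(outdir, "validate", config, [outdir / "prediction.tif", outdir / "truth_labels.tif"])


def stage_drivers(config: SceneConfig, outdir: Path, n_each: int = 5000, n_cells: int = 2000) -> None:
    _require(outdir, "drivers")
    pred = _load_prediction(config, outdir)
    driver_names = [n for n in config.driver_effects] + ["nuisance"]
    layers = {n: read_raster(outdir / f"driver_{n}.tif") for n in driver_names}
    reg = sample_regional(pred, layers, n_each=n_each, seed=config.seed + 4)
    reg.data.to_csv(outdir / "sample_regional.csv", index=False)
    tab = explained_deviance_table(reg, driver_names)
    tab["scale"] = "regional"
    frac = read_raster(outdir / "fraction_coarse.tif")
    counts = _coarse_forest_counts(pred, config.coarse_factor)
    coarse_layers = {n: _coarse_mean(layers[n], config.coarse_factor) for n in driver_names}
    co = sample_coarse(frac, counts, coarse_layers, n_cells=n_cells, seed=config.seed + 5)
    co.data.to_csv(outdir / "sample_coarse.csv", index=False)
    tab2 = explained_deviance_table(co, driver_names)
    tab2["scale"] = "broad"
    pd.concat([tab, tab2], ignore_index=True).to_csv(outdir / "driver_deviance.csv", index=False)
    write_manifest(outdir, "drivers", config, [outdir / "prediction.tif"])


def _coarse_forest_counts(pred: PredictionRaster, factor: int) -> np.ndarray:
    from .classifier import _block_sums

    return _block_sums(pred.predicted_mask, factor)


def _coarse_mean(layer: np.ndarray, factor: int) -> np.ndarray:
    from .classifier import _block_sums

    return _block_sums(layer, factor) / _block_sums(np.ones_like(layer), factor)


def stage_persistence(config: SceneConfig, outdir: Path, min_pixels: int = 10) -> None:
    _require(outdir, "persistence")
    pred = _load_prediction(config, outdir)
    s1 = read_raster(outdir / "spring_y1.tif")
    s2 = read_raster(outdir / "spring_y2.tif")
    cells = cell_persistence(pred, s1, s2, config.coarse_factor, min_pixels)
    cells.to_csv(outdir / "persistence_cells.csv", index=False)
    nrows = int(cells["cell_row"].max()) + 1
    ncols = int(cells["cell_col"].max()) + 1
    delta_map = np.full((nrows, ncols), np.nan)
    delta_map[cells["cell_row"], cells["cell_col"]] = cells["delta"]
    write_raster(outdir / "persistence_delta.tif", delta_map)
    preds = {
        "mean_change_time": aggregate_cat_to_cells(
            read_raster(outdir / "cat_change_time.tif"), pred, config.coarse_factor
        ),
        "mean_change_magnitude": aggregate_cat_to_cells(
            read_raster(outdir / "cat_change_magnitude.tif"), pred, config.coarse_factor
        ),
    }
    try:
        persistence_driver_models(cells, preds).to_csv(outdir / "persistence_deviance.csv", index=False)
    except ValueError as exc:
        warnings.warn(f"persistence driver models skipped: {exc}")
    write_manifest(outdir, "persistence", config, [outdir / "prediction.tif", outdir / "spring_y1.tif"])


def apply_forest_mask(cover: np.ndarray, threshold: float = 0.80) -> np.ndarray:
    """Boolean forest mask from a tree-cover raster.

    Accepts fractional ([0, 1]) or percent ([0, 100]) cover, auto-detected;
    the threshold comparison is inclusive (cover ≥ 80% is forest).
    """
    cover = np.asarray(cover, float)
    finite = cover[np.isfinite(cover)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ValueError("cover values must lie in [0, 1] or [0, 100]")
    if finite.size and finite.max() > 1.5:
        cover = cover / 100.0
    return cover >= threshold


def run_stage(stage: str, config: SceneConfig, outdir: Path, **kwargs) -> None:
    fns = {
        "simulate": stage_simulate,
        "features": stage_features,
        "train": stage_train,
        "predict": stage_predict,
        "validate": stage_validate,
        "drivers": stage_drivers,
        "persistence": stage_persistence,
    }
    if stage not in fns:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    fns[stage](config, outdir, **kwargs)


def run_all(config: SceneConfig, outdir: Path) -> None:
    for stage in STAGES:
        run_stage(stage, config, outdir)
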