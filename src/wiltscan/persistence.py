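"""Following-spring greenness effect of early wilting.

Within each coarse cell the median May/June NDVI of wilted (NDVI_b) and
non-wilted (NDVI_g) forest pixels is computed for the drought year and the
following spring; the persistence delta

    delta = (NDVI_g − NDVI_b)_year2 − (NDVI_g − NDVI_b)_year1

measures how much further the wilted patches fell behind.  A second stage
relates the cell deltas to environmental drivers and to the timing and
magnitude of the summer change point with Gaussian additive models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import PredictionRaster
from .drivers import fit_driver_model


def _cell_slices(n: int, factor: int) -> list[slice]:
    return [slice(i, min(i + factor, n)) for i in range(0, n, factor)]


def cell_persistence(
    pred: PredictionRaster,
    spring_y1: np.ndarray,
    spring_y2: np.ndarray,
    factor: int,
    min_pixels: int = 10,
) -> pd.DataFrame:
    """Per-cell medians of both classes in both springs, and the delta.

    ``spring_y1``/``spring_y2`` are per-pixel mean May/June NDVI rasters.
    Cells where either class has fewer than ``min_pixels`` pixels with a
    defined value in either year get NaN delta.
    """
    if spring_y1.shape != pred.classes.shape or spring_y2.shape != pred.classes.shape:
        raise ValueError("raster grids do not match the prediction map")
    wilted = pred.presence_mask
    green = pred.classes == 0
    rows = []
    for ci, rs in enumerate(_cell_slices(pred.classes.shape[0], factor)):
        for cj, cs in enumerate(_cell_slices(pred.classes.shape[1], factor)):
            rec: dict = {"cell_row": ci, "cell_col": cj}
            ok = True
            for tag, cls_mask in (("b", wilted), ("g", green)):
                cm = cls_mask[rs, cs]
                for yr, ras in (("y1", spring_y1), ("y2", spring_y2)):
                    v = ras[rs, cs][cm]
                    v = v[np.isfinite(v)]
                    rec[f"ndvi_{tag}_{yr}"] = np.median(v) if v.size >= min_pixels else np.nan
                    rec[f"n_{tag}_{yr}"] = int(v.size)
                    ok &= v.size >= min_pixels
            if ok:
                rec["delta"] = (rec["ndvi_g_y2"] - rec["ndvi_b_y2"]) - (
                    rec["ndvi_g_y1"] - rec["ndvi_b_y1"]
                )
            else:
                rec["delta"] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_cat_to_cells(
    cat_layer: np.ndarray, pred: PredictionRaster, factor: int
) -> np.ndarray:
    """Mean of a per-pixel CAT statistic over wilted pixels per coarse cell."""
    wilted = pred.presence_mask
    nr = len(_cell_slices(pred.classes.shape[0], factor))
    nc = len(_cell_slices(pred.classes.shape[1], factor))
    out = np.full((nr, nc), np.nan)
    for ci, rs in enumerate(_cell_slices(pred.classes.shape[0], factor)):
        for cj, cs in enumerate(_cell_slices(pred.classes.shape[1], factor)):
            v = cat_layer[rs, cs][wilted[rs, cs]]
            v = v[np.isfinite(v)]
            if v.size:
                out[ci, cj] = v.mean()
    return out


def persistence_driver_models(
    cells: pd.DataFrame,
    predictor_layers: dict[str, np.ndarray],
    min_cells: int = 50,
) -> pd.DataFrame:
    """Univariate and multivariate Gaussian GAMs of delta on cell predictors.

    ``predictor_layers`` maps names to coarse-grid rasters indexed by
    (cell_row, cell_col).  Returns an explained-deviance table.
    """
    data = cells.copy()
    for name, layer in predictor_layers.items():
        data[name] = layer[data["cell_row"].to_numpy(), data["cell_col"].to_numpy()]
    names = list(predictor_layers)
    keep = np.isfinite(data["delta"].to_numpy())
    for name in names:
        keep &= np.isfinite(data[name].to_numpy(float))
    data = data.loc[keep]
    if len(data) < min_cells:
        raise ValueError(f"only {len(data)} usable cells (need >= {min_cells})")
    delta = data["delta"].to_numpy(float)
    rows = []
    for d in names:
        s = fit_driver_model(data, [d], family="gaussian", response=delta)
        rows.append({"model": s.model_id, "explained_deviance": s.explained_deviance})
    s = fit_driver_model(data, names, family="gaussian", response=delta)
    rows.append({"model": s.model_id, "explained_deviance": s.explained_deviance})
    return pd.DataFrame(rows)
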