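"""Early-wilting classification: labels → trained forest → wall-to-wall maps.

The classifier is a random forest grown with class-stratified per-tree
bootstraps: each tree sees up to ``presence_n`` presence pixels and
``absence_n`` absence-or-artifact pixels drawn with replacement, which
deliberately over-represents the rarer presence class relative to the
landscape.  Predictions are majority votes; coarse-scale products report
the fraction of predicted forest pixels that wilted per aggregation cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .scene import LabelPolygon

NOT_PREDICTED = 255
LABEL_PRIORITY = {"presence": 2, "artifact": 1, "absence": 0}


@dataclass
class PredictionRaster:
    """Wall-to-wall presence/absence map.

    ``classes`` is uint8: 1 presence, 0 absence, 255 not-predicted
    (non-forest, or forest with incomplete features — the latter are
    mapped as absence for display but excluded from area denominators).
    """

    classes: np.ndarray
    vote_fraction: np.ndarray  # NaN where not predicted
    forest_mask: np.ndarray
    pixel_size: float

    @property
    def predicted_mask(self) -> np.ndarray:
        return self.classes != NOT_PREDICTED

    @property
    def presence_mask(self) -> np.ndarray:
        return self.classes == 1


def rasterize_labels(
    polygons: list[LabelPolygon], shape: tuple[int, int], pixel_size: float
) -> tuple[pd.DataFrame, int]:
    """Pixel-center containment rasterization of labeled polygons.

    Overlap conflicts resolve presence > artifact > absence; the number of
    pixels receiving conflicting labels is returned alongside.
    """
    if not polygons:
        raise ValueError("no polygons given")
    rows_, cols_, labs_ = [], [], []
    for poly in polygons:
        minx, miny, maxx, maxy = poly.geometry.bounds
        c0 = max(int(np.floor(minx / pixel_size - 0.5)), 0)
        c1 = min(int(np.ceil(maxx / pixel_size)), shape[1] - 1)
        r0 = max(int(np.floor(miny / pixel_size - 0.5)), 0)
        r1 = min(int(np.ceil(maxy / pixel_size)), shape[0] - 1)
        if c1 < c0 or r1 < r0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
        x = (cc.ravel() + 0.5) * pixel_size
        y = (rr.ravel() + 0.5) * pixel_size
        inside = shapely.contains_xy(poly.geometry, x, y)
        rows_.append(rr.ravel()[inside])
        cols_.append(cc.ravel()[inside])
        labs_.extend([poly.label] * int(inside.sum()))
    if not rows_ or sum(len(r) for r in rows_) == 0:
        raise ValueError("polygons label zero pixels on this grid")
    df = pd.DataFrame(
        {
            "row": np.concatenate(rows_),
            "col": np.concatenate(cols_),
            "label": labs_,
        }
    )
    df["prio"] = df["label"].map(LABEL_PRIORITY)
    grouped = df.groupby(["row", "col"], as_index=False)
    n_conflicts = int((grouped["label"].nunique()["label"] > 1).sum())
    out = df.sort_values("prio", ascending=False).drop_duplicates(["row", "col"])
    return out[["row", "col", "label"]].reset_index(drop=True), n_conflicts


def build_training_set(
    labeled: pd.DataFrame, features: np.ndarray, complete: np.ndarray, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (X, y, flat pixel index) from labeled pixels with complete features.

    Presence → 1; absence and artifacts → 0 (artifact counts are logged).
    """
    flat = labeled["row"].to_numpy() * shape[1] + labeled["col"].to_numpy()
    keep = complete[flat]
    flat = flat[keep]
    labels = labeled["label"].to_numpy()[keep]
    n_art = int((labels == "artifact").sum())
    if n_art:
        logging.getLogger(__name__).info(
            "%d artifact pixels merged into the negative class", n_art
        )
    y = (labels == "presence").astype(int)
    return features[flat], y, flat


class WiltingClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with class-stratified per-tree bootstrap sampling.

    Parameters
    ----------
    n_trees : number of classification trees (default 500).
    presence_n, absence_n : per-tree bootstrap sizes for the positive and
        negative class; taken as "up to" (capped at the class size), drawn
        with replacement.
    threshold : presence-vote fraction above which a pixel is classified
        presence (0.5 = majority vote).
    oob_score : if True, compute out-of-bag accuracy into ``oob_score_``.
    random_state : seed; identical seeds give identical forests.
    """

    def __init__(
        self,
        n_trees: int = 500,
        presence_n: int = 75_000,
        absence_n: int = 20_000,
        threshold: float = 0.5,
        max_features: str | float = "sqrt",
        oob_score: bool = False,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.presence_n = presence_n
        self.absence_n = absence_n
        self.threshold = threshold
        self.max_features = max_features
        self.oob_score = oob_score
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y).astype(int)
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_trees < 1 or self.presence_n < 1 or self.absence_n < 1:
            raise ValueError("tree and sample counts must be positive")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(self.random_state)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        n_pos = min(self.presence_n, pos.size)
        n_neg = min(self.absence_n, neg.size)
        self.estimators_ = []
        oob_votes = np.zeros(len(y))
        oob_cnt = np.zeros(len(y))
        for _ in range(self.n_trees):
            idx = np.concatenate(
                [rng.choice(pos, n_pos, replace=True), rng.choice(neg, n_neg, replace=True)]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.estimators_.append(tree)
            if self.oob_score:
                out = np.ones(len(y), dtype=bool)
                out[idx] = False
                if out.any():
                    oob_votes[out] += tree.predict(X[out])
                    oob_cnt[out] += 1
        if self.oob_score:
            seen = oob_cnt > 0
            pred = (oob_votes[seen] / oob_cnt[seen]) >= self.threshold
            self.oob_score_ = float((pred.astype(int) == y[seen]).mean())
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        votes = np.zeros(X.shape[0])
        for tree in self.estimators_:
            votes += tree.predict(X)
        frac = votes / len(self.estimators_)
        return np.column_stack([1 - frac, frac])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


def predict_wilting(
    model: WiltingClassifier,
    features: np.ndarray,
    complete: np.ndarray,
    forest_mask: np.ndarray,
    pixel_size: float = 10.0,
) -> PredictionRaster:
    """Wall-to-wall prediction over forest pixels with complete features."""
    shape = forest_mask.shape
    if features.shape[0] != forest_mask.size:
        raise ValueError("feature stack does not match the grid")
    classes = np.full(shape, NOT_PREDICTED, dtype=np.uint8)
    votes = np.full(shape, np.nan, dtype=np.float32)
    sel = forest_mask.ravel() & complete
    if sel.any():
        frac = model.predict_proba(features[sel])[:, 1]
        flat_cls = classes.ravel()
        flat_cls[sel] = (frac >= model.threshold).astype(np.uint8)
        classes = flat_cls.reshape(shape)
        flat_v = votes.ravel()
        flat_v[sel] = frac
        votes = flat_v.reshape(shape)
    return PredictionRaster(classes, votes, forest_mask, pixel_size)


def _block_sums(arr: np.ndarray, factor: int) -> np.ndarray:
    """Sum over factor×factor blocks; edge blocks use the available pixels."""
    r, c = arr.shape
    row_idx = np.arange(0, r, factor)
    col_idx = np.arange(0, c, factor)
    return np.add.reduceat(np.add.reduceat(arr.astype(float), row_idx, axis=0), col_idx, axis=1)


def aggregate_fraction(pred: PredictionRaster, factor: int) -> np.ndarray:
    """Per-cell fraction of predicted forest pixels classified presence.

    Cells containing zero predicted pixels are NaN.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    presence = _block_sums(pred.presence_mask, factor)
    predicted = _block_sums(pred.predicted_mask, factor)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = presence / predicted
    frac[predicted == 0] = np.nan
    return frac
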