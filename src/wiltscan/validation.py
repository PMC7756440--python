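"""Design-based accuracy assessment and area estimation.

Post-stratified ("good practices") estimators for maps validated with a
stratified random reference sample: the per-stratum error matrix is
weighted by mapped-area proportions W_i, giving unbiased estimates of
overall accuracy, user's/producer's accuracies and reference-class areas
with standard errors.  Implemented for k classes; the early-wilting map
uses k = 2 (stratum 0 = predicted presence, stratum 1 = predicted
absence), so user's accuracy of the presence stratum is the positive
predictive value and of the absence stratum the negative predictive value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classifier import PredictionRaster
from .scene import SceneTruth

Z95 = 1.959963984540054


@dataclass
class StratifiedTestDesign:
    """Mapped-area stratum weights and evaluated sample sizes."""

    weights: np.ndarray  # W_i, sums to 1
    n: np.ndarray        # evaluated reference samples per stratum

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.n = np.asarray(self.n, int)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("stratum weights must sum to 1")
        if np.any(self.n < 2):
            raise ValueError("every stratum needs n_i >= 2 evaluated samples")


@dataclass
class AccuracyReport:
    overall_accuracy: float
    overall_accuracy_se: float
    users_accuracy: np.ndarray
    users_accuracy_se: np.ndarray
    producers_accuracy: np.ndarray
    producers_accuracy_se: np.ndarray

    def ci(self, which: str = "overall") -> tuple[float, float]:
        if which == "overall":
            return (
                self.overall_accuracy - Z95 * self.overall_accuracy_se,
                self.overall_accuracy + Z95 * self.overall_accuracy_se,
            )
        raise ValueError(which)


@dataclass
class AreaEstimate:
    proportions: np.ndarray      # p̂_·j per reference class
    proportions_se: np.ndarray
    areas: np.ndarray            # in units of total_area
    areas_se: np.ndarray
    total_area: float

    def ci(self, j: int) -> tuple[float, float]:
        return (
            self.areas[j] - Z95 * self.areas_se[j],
            self.areas[j] + Z95 * self.areas_se[j],
        )


def _check_matrix(matrix: np.ndarray, design: StratifiedTestDesign) -> np.ndarray:
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != design.weights.size:
        raise ValueError("error matrix rows must align with design strata")
    if np.any(m < 0):
        raise ValueError("error-matrix counts must be non-negative")
    if not np.array_equal(m.sum(axis=1), design.n):
        raise ValueError("row sums must equal the design's per-stratum sample sizes")
    return m


def post_stratified_accuracy(matrix: np.ndarray, design: StratifiedTestDesign) -> AccuracyReport:
    """Post-stratified overall, user's and producer's accuracy with SEs.

    With estimated cell proportions p̂_ij = W_i · n_ij / n_i·:
    OA = Σ_j p̂_jj,  SE(OA) = sqrt(Σ_i W_i² UA_i(1−UA_i)/(n_i·−1));
    UA_i = n_ii/n_i·,  SE(UA_i) = sqrt(UA_i(1−UA_i)/(n_i·−1));
    PA_j = p̂_jj/p̂_·j with its delta-method standard error.
    """
    m = _check_matrix(matrix, design)
    W = design.weights
    n = design.n.astype(float)
    p = W[:, None] * m / n[:, None]
    k = W.size
    ua = np.diag(m) / n
    ua_se = np.sqrt(ua * (1 - ua) / (n - 1))
    oa = float(np.trace(p))
    oa_se = float(np.sqrt(np.sum(W**2 * ua * (1 - ua) / (n - 1))))

    p_col = p.sum(axis=0)
    pa = np.full(k, np.nan)
    pa_se = np.full(k, np.nan)
    for j in range(k):
        if p_col[j] <= 0:
            warnings.warn(f"reference class {j} absent from the sample; PA undefined")
            continue
        pa[j] = p[j, j] / p_col[j]
        # delta-method variance (mapped-proportion form; total map size cancels)
        term1 = W[j] ** 2 * (1 - pa[j]) ** 2 * ua[j] * (1 - ua[j]) / (n[j] - 1)
        others = [
            W[i] ** 2 * (m[i, j] / n[i]) * (1 - m[i, j] / n[i]) / (n[i] - 1)
            for i in range(k)
            if i != j
        ]
        term2 = pa[j] ** 2 * float(np.sum(others))
        pa_se[j] = np.sqrt((term1 + term2) / p_col[j] ** 2)
    return AccuracyReport(oa, oa_se, ua, ua_se, pa, pa_se)


def estimate_area(
    matrix: np.ndarray, design: StratifiedTestDesign, total_area: float
) -> AreaEstimate:
    """Post-stratified reference-class proportions and areas with SEs.

    p̂_·j = Σ_i W_i n_ij/n_i·;
    SE(p̂_·j) = sqrt(Σ_i W_i² (n_ij/n_i·)(1 − n_ij/n_i·)/(n_i·−1));
    Â_j = p̂_·j · total_area, SE scaled accordingly.
    """
    if total_area <= 0:
        raise ValueError("total_area must be positive")
    m = _check_matrix(matrix, design)
    W = design.weights
    n = design.n.astype(float)
    frac = m / n[:, None]
    p_col = (W[:, None] * frac).sum(axis=0)
    var = (W[:, None] ** 2 * frac * (1 - frac) / (n[:, None] - 1)).sum(axis=0)
    se = np.sqrt(var)
    return AreaEstimate(p_col, se, p_col * total_area, se * total_area, total_area)


def draw_test_sample(
    pred: PredictionRaster,
    truth: SceneTruth,
    n_per_stratum: int = 3000,
    seed: int | None = None,
) -> tuple[np.ndarray, StratifiedTestDesign]:
    """Stratified reference sample from the prediction map, scored on truth.

    Simple random sampling without replacement of ``n_per_stratum`` pixels
    per predicted stratum (presence, absence); the generator's truth label
    stands in for visual interpretation.  Not-predicted pixels are outside
    the frame, so stratum weights are mapped proportions among predicted
    pixels only.  Returns a 2×2 error matrix (rows = predicted
    [presence, absence], cols = reference) and the matching design.
    """
    rng = np.random.default_rng(seed)
    cls = pred.classes.ravel()
    ref = truth.labels.ravel()
    strata = [np.flatnonzero(cls == 1), np.flatnonzero(cls == 0)]
    if any(s.size == 0 for s in strata):
        raise ValueError("both predicted strata must be non-empty")
    counts = np.array([s.size for s in strata], float)
    weights = counts / counts.sum()
    matrix = np.zeros((2, 2), dtype=int)
    n_out = []
    for i, s in enumerate(strata):
        take = n_per_stratum
        if s.size < n_per_stratum:
            warnings.warn(f"stratum {i} has only {s.size} pixels; sampling all")
            take = s.size
        pick = rng.choice(s, size=take, replace=False)
        n_pres = int(ref[pick].sum())
        matrix[i, 0] = n_pres
        matrix[i, 1] = take - n_pres
        n_out.append(take)
    return matrix, StratifiedTestDesign(weights, np.array(n_out))
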