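"""Synthetic drought-wilting landscape generator.

Emulates the statistical structure of a 10 m optical vegetation-index
archive over one drought summer: spatially autocorrelated environmental
driver fields, a wilting subpopulation whose probability follows a known
logistic link on those drivers, per-pixel NDVI time series with a
double-logistic phenology, observation noise, cloud gaps, an abrupt
late-summer NDVI drop in wilted pixels, grassland/bare-soil artifact
pixels, and a reduced next-spring NDVI for wilted pixels.

Everything is deterministic given the config seed, and the generator keeps
full truth (labels, onset days, probabilities), so each downstream stage
of the analysis can be validated against a known answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import box

# --- calendar (serial day 1 = Jan 1, 2018; 2019 days continue past 365) ---
DOY_MAR1, DOY_APR30 = 60, 120
DOY_MAY1, DOY_JUN30 = 121, 181
DOY_AUG1, DOY_SEP15, DOY_SEP30 = 213, 258, 273
DOY_OCT1, DOY_NOV30 = 274, 334
DOY_MAY1_Y2, DOY_JUN30_Y2 = 365 + 121, 365 + 181

WINDOW_SPRING = (DOY_MAR1, DOY_APR30)
WINDOW_SUMMER = (DOY_MAY1, DOY_SEP30)
WINDOW_FALL = (DOY_OCT1, DOY_NOV30)
WINDOW_EARLY_SUMMER_Y1 = (DOY_MAY1, DOY_JUN30)
WINDOW_EARLY_SUMMER_Y2 = (DOY_MAY1_Y2, DOY_JUN30_Y2)

CLASS_FOREST, CLASS_GRASSLAND, CLASS_BARE = 0, 1, 2


@dataclass(frozen=True)
class Phenology:
    """Double-logistic seasonal NDVI curve.

    ndvi(t) = winter + (summer − winter) ·
              [logistic(r_up·(t − t_up)) − logistic(r_down·(t − t_down))]
    """

    winter_ndvi: float = 0.35
    summer_ndvi: float = 0.85
    greenup_day: float = 110.0
    greenup_rate: float = 0.12
    senescence_day: float = 295.0
    senescence_rate: float = 0.10

    def __call__(self, day: np.ndarray) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        amp = self.summer_ndvi - self.winter_ndvi
        up = expit(self.greenup_rate * (day - self.greenup_day))
        down = expit(self.senescence_rate * (day - self.senescence_day))
        return self.winter_ndvi + amp * (up - down)


#: driver name -> (mean, sd, lower clip, upper clip).  NaN clip = unbounded.
#: Ranges are plausible for temperate Central European forest landscapes.
DRIVER_SPECS: dict[str, tuple[float, float, float, float]] = {
    "veg_height": (18.0, 6.0, 0.0, 45.0),            # m
    "dist_forest_edge": (150.0, 100.0, 0.0, np.nan),  # m
    "forest_mixture": (0.5, 0.25, 0.0, 1.0),          # fraction broadleaved
    "slope": (15.0, 10.0, 0.0, 60.0),                 # degrees
    "exposition_ns": (0.0, 0.5, -1.0, 1.0),           # south(−)/north(+)
    "rooting_depth": (3.0, 1.2, 1.0, 5.0),            # ordinal class
    "hydraulic_conductivity": (2.5, 1.0, 0.5, 5.0),
    "aug_soil_moisture": (0.45, 0.12, 0.05, 0.95),    # saturation fraction
    "aug_soil_moisture_anom": (-30.0, 15.0, -90.0, 40.0),   # % of baseline − 100
    "aug_tmax": (26.0, 3.0, np.nan, np.nan),          # °C
    "aug_tmax_anom": (3.0, 1.2, np.nan, np.nan),      # °C
    "prior_year_tmax_anom": (1.0, 0.8, np.nan, np.nan),     # °C
    "apr_aug_precip": (450.0, 150.0, 50.0, np.nan),   # mm
    "aug_precip_anom": (45.0, 20.0, 0.0, 160.0),      # % of baseline
    "prior_year_precip_anom": (85.0, 15.0, 20.0, 160.0),    # % of baseline
}

#: an unclipped, zero-mean driver suitable for exact moment checks
UNCLIPPED_DRIVERS = ("aug_tmax", "aug_tmax_anom", "prior_year_tmax_anom")

DEFAULT_DRIVER_EFFECTS: dict[str, tuple[float, float]] = {
    "aug_tmax_anom": (1.0, 0.0),
    "aug_precip_anom": (-0.8, 0.0),
    "veg_height": (0.0, -0.6),
    "slope": (0.4, 0.0),
    "rooting_depth": (-0.3, 0.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene; all randomness flows from ``seed``."""

    grid_rows: int = 200
    grid_cols: int = 200
    pixel_size: float = 10.0
    coarse_factor: int = 50
    revisit_days: float = 4.0
    cloud_gap_prob: float = 0.3
    noise_sd: float = 0.05
    phenology: Phenology = field(default_factory=Phenology)
    wilt_onset_window: tuple[int, int] = (DOY_AUG1, DOY_SEP15)
    wilt_drop: float = 0.3
    wilt_ramp_days: float = 3.0
    persistence_delta: float = 0.015
    driver_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DRIVER_EFFECTS)
    )
    artifact_fraction: float = 0.1
    mask_leakage: float = 0.03     # grassland fraction inside the mapped forest mask
    pixel_offset_sd: float = 0.05  # per-pixel baseline NDVI variability
    prevalence_target: float = 0.108
    smoothing_length: float = 5.0  # pixels; 0 → white noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if min(self.grid_rows, self.grid_cols) < self.coarse_factor:
            raise ValueError("grid dimensions must be >= coarse_factor")
        for name, p in [
            ("cloud_gap_prob", self.cloud_gap_prob),
            ("artifact_fraction", self.artifact_fraction),
            ("prevalence_target", self.prevalence_target),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.wilt_drop <= 0:
            raise ValueError("wilt_drop must be positive")
        if not 3.0 <= self.revisit_days <= 5.0:
            raise ValueError("revisit_days must be in [3, 5]")

    def with_seed(self, seed: int) -> "SceneConfig":
        return replace(self, seed=seed)


@dataclass
class DriverRasters:
    """Named environmental driver fields plus forest mask and nuisance noise."""

    layers: dict[str, np.ndarray]
    forest_mask: np.ndarray
    artifact_class: np.ndarray  # CLASS_FOREST / CLASS_GRASSLAND / CLASS_BARE

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.forest_mask.shape


@dataclass
class SceneTruth:
    """Known per-pixel truth of a generated scene."""

    probability: np.ndarray        # wilting probability, [0,1], NaN off-forest
    labels: np.ndarray             # bool, True = wilted (forest only)
    onset_day: np.ndarray          # float day-of-year, NaN where not wilted
    artifact_class: np.ndarray
    forest_mask: np.ndarray
    pixel_size: float

    @property
    def wilted_count(self) -> int:
        return int(self.labels.sum())

    @property
    def wilted_area_m2(self) -> float:
        return self.wilted_count * self.pixel_size**2


@dataclass
class NdviStack:
    """Per-pixel NDVI observations on a shared date grid (pixels flattened row-major)."""

    dates: np.ndarray    # (T,) serial days
    values: np.ndarray   # (n_pixels, T) float32
    valid: np.ndarray    # (n_pixels, T) bool
    shape: tuple[int, int]

    def series(self, row: int, col: int) -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
        i = row * self.shape[1] + col
        return self.dates, self.values[i], self.valid[i]


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian random field with correlation length sigma."""
    white = rng.standard_normal(shape)
    if sigma <= 0:
        return white
    sm = gaussian_filter(white, sigma=sigma, mode="wrap")
    # exact variance attenuation of the discrete kernel, via an impulse response
    size = int(8 * sigma) | 1
    imp = np.zeros((size, size))
    imp[size // 2, size // 2] = 1.0
    resp = gaussian_filter(imp, sigma=sigma, mode="constant")
    return sm / np.sqrt((resp**2).sum())


def generate_drivers(config: SceneConfig) -> DriverRasters:
    """Generate spatially autocorrelated driver fields, forest mask and artifacts.

    Each driver is smoothed seeded white noise rescaled to the stated
    mean/sd and clipped to its physical range; the nuisance driver is pure
    independent noise.  The forest mask covers exactly
    ``1 − artifact_fraction`` of the scene (empirical quantile threshold on
    a smoothed field, so non-forest comes in patches); non-forest splits
    evenly into grassland and bare soil.
    """
    shape = (config.grid_rows, config.grid_cols)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    layers: dict[str, np.ndarray] = {}
    for name, (mean, sd, lo, hi) in DRIVER_SPECS.items():
        f = mean + sd * _smoothed_field(rng, shape, config.smoothing_length)
        if np.isfinite(lo):
            f = np.maximum(f, lo)
        if np.isfinite(hi):
            f = np.minimum(f, hi)
        layers[name] = f
    layers["nuisance"] = rng.standard_normal(shape)

    land = _smoothed_field(rng, shape, config.smoothing_length)
    if config.artifact_fraction > 0:
        thr = np.quantile(land, config.artifact_fraction)
        forest = land > thr
    else:
        forest = np.ones(shape, dtype=bool)
    artifact = np.full(shape, CLASS_FOREST, dtype=np.uint8)
    nonforest = ~forest
    # split non-forest patches into grassland vs bare by a second field
    split = _smoothed_field(rng, shape, config.smoothing_length) > 0
    artifact[nonforest & split] = CLASS_GRASSLAND
    artifact[nonforest & ~split] = CLASS_BARE
    # mask commission error: patches of true grassland inside the mapped mask
    if config.mask_leakage > 0:
        leak_field = _smoothed_field(rng, shape, config.smoothing_length)
        thr_leak = np.quantile(leak_field[forest], config.mask_leakage)
        artifact[forest & (leak_field <= thr_leak)] = CLASS_GRASSLAND
    return DriverRasters(layers=layers, forest_mask=forest, artifact_class=artifact)


def compute_wilting_probability(
    drivers: DriverRasters,
    effects: Mapping[str, tuple[float, float]],
    prevalence_target: float,
    tol: float = 1e-3,
) -> np.ndarray:
    """Logistic-link wilting probability with auto-calibrated intercept.

    ``p = expit(b0 + Σ_d lin_d·z_d + quad_d·z_d²)`` with drivers
    standardized over forest pixels; ``b0`` is found by bisection so the
    forest-mask mean of p matches ``prevalence_target`` within ``tol``.
    Vegetation height, when present, must enter concavely (unimodal risk).
    """
    for name in effects:
        if name not in drivers.layers:
            raise KeyError(f"unknown driver {name!r}")
    if "veg_height" in effects and effects["veg_height"][1] >= 0 and effects["veg_height"][0] == 0:
        warnings.warn("veg_height effect is not concave; expected a unimodal response")
    fmask = drivers.forest_mask
    eta = np.zeros(drivers.shape, dtype=float)
    for name, (lin, quad) in effects.items():
        layer = drivers[name]
        mu, sd = layer[fmask].mean(), layer[fmask].std()
        z = (layer - mu) / sd if sd > 0 else np.zeros_like(layer)
        eta += lin * z + quad * z**2

    eta_f = eta[fmask]

    def mean_p(b0: float) -> float:
        return float(expit(b0 + eta_f).mean())

    lo, hi = -30.0, 30.0
    b0 = 0.0
    for _ in range(200):
        b0 = 0.5 * (lo + hi)
        m = mean_p(b0)
        if abs(m - prevalence_target) < tol * 0.1:
            break
        if m < prevalence_target:
            lo = b0
        else:
            hi = b0
    p = expit(b0 + eta)
    p[~fmask] = np.nan
    return p


def sample_labels(
    probability: np.ndarray,
    drivers: DriverRasters,
    config: SceneConfig,
) -> SceneTruth:
    """Independent Bernoulli wilting draws per forest pixel, with onset days."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    fmask = drivers.forest_mask
    p = np.nan_to_num(probability, nan=0.0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    # wilting can only befall actual forest; mapped-mask grassland stays false
    true_forest = fmask & (drivers.artifact_class == CLASS_FOREST)
    labels = (rng.random(p.shape) < p) & true_forest
    onset = np.full(p.shape, np.nan)
    d0, d1 = config.wilt_onset_window
    onset[labels] = rng.uniform(d0, d1, size=int(labels.sum()))
    return SceneTruth(
        probability=probability,
        labels=labels,
        onset_day=onset,
        artifact_class=drivers.artifact_class,
        forest_mask=fmask,
        pixel_size=config.pixel_size,
    )


def _observation_dates(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Shared observation calendar: 2018 Mar 1–Nov 30 plus 2019 May 1–Jun 30.

    Gaps are integer days uniform on [revisit_days − 1, revisit_days + 1]
    (mean = revisit_days), drawn once per scene as for a satellite tile.
    """

    def run(start: int, stop: int) -> list[int]:
        days = [start]
        while True:
            gap = int(rng.integers(round(config.revisit_days) - 1, round(config.revisit_days) + 2))
            if days[-1] + gap > stop:
                break
            days.append(days[-1] + gap)
        return days

    d18 = run(DOY_MAR1, DOY_NOV30)
    d19 = run(DOY_MAY1_Y2, DOY_JUN30_Y2)
    return np.array(d18 + d19, dtype=int)


def _grass_curve(day: np.ndarray, pheno: Phenology) -> np.ndarray:
    """Grassland trajectory: lower spring NDVI and a mid-July senescence dip."""
    base = Phenology(
        winter_ndvi=0.20,
        summer_ndvi=0.70,
        greenup_day=pheno.greenup_day + 10,
        greenup_rate=pheno.greenup_rate,
        senescence_day=pheno.senescence_day,
        senescence_rate=pheno.senescence_rate,
    )(day)
    dip = 0.30 * expit(0.25 * (np.asarray(day, float) - 190)) * expit(-0.25 * (np.asarray(day, float) - 235))
    return base - dip


def generate_ndvi_series(truth: SceneTruth, config: SceneConfig) -> NdviStack:
    """Per-pixel NDVI observations for the drought year and the following spring.

    Non-wilted forest follows the phenology curve; wilted pixels drop by
    ``wilt_drop`` over a ``wilt_ramp_days`` linear ramp from their onset
    day and show a ``persistence_delta`` lower NDVI the next spring.
    Grassland senesces in mid-summer; bare soil stays low and flat.
    Observations get N(0, noise_sd) noise, are dropped i.i.d. with
    probability ``cloud_gap_prob``, and are clipped to [−1, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 303]))
    dates = _observation_dates(config, rng)
    doy = np.where(dates > 365, dates - 365, dates).astype(float)
    is_y2 = dates > 365
    n_pix = truth.labels.size
    pheno = config.phenology

    forest_curve = pheno(doy)
    grass = _grass_curve(doy, pheno)
    bare = np.full(doy.shape, 0.15)

    cls = truth.artifact_class.ravel()
    values = np.empty((n_pix, dates.size), dtype=np.float32)
    values[:] = forest_curve[None, :]
    values[cls == CLASS_GRASSLAND] = grass[None, :]
    values[cls == CLASS_BARE] = bare[None, :]

    wilted = truth.labels.ravel()
    if wilted.any():
        onset = truth.onset_day.ravel()[wilted][:, None]
        t = dates[None, :].astype(float)
        ramp = np.clip((t - onset) / config.wilt_ramp_days, 0.0, 1.0)
        ramp[:, is_y2] = 0.0  # next spring handled via persistence_delta
        w = values[wilted]
        w -= (config.wilt_drop * ramp).astype(np.float32)
        w[:, is_y2] -= np.float32(config.persistence_delta)
        values[wilted] = w

    if config.pixel_offset_sd > 0:
        values += rng.normal(0.0, config.pixel_offset_sd, size=(n_pix, 1)).astype(np.float32)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape).astype(np.float32)
    np.clip(values, -1.0, 1.0, out=values)
    valid = rng.random(values.shape) >= config.cloud_gap_prob
    return NdviStack(dates=dates, values=values, valid=valid, shape=truth.labels.shape)


def generate_scene(config: SceneConfig) -> tuple[DriverRasters, SceneTruth, NdviStack]:
    """Full scene: drivers → probabilities → labels → NDVI stack."""
    drivers = generate_drivers(config)
    prob = compute_wilting_probability(drivers, config.driver_effects, config.prevalence_target)
    truth = sample_labels(prob, drivers, config)
    stack = generate_ndvi_series(truth, config)
    return drivers, truth, stack


# ---------------------------------------------------------------------------
# climate statistics (mean/anomaly semantics used for the weather drivers)
# ---------------------------------------------------------------------------

#: the 15 canonical single/consecutive-month periods April–August
CANONICAL_PERIODS: list[tuple[int, ...]] = [
    tuple(range(a, b + 1)) for a in range(4, 9) for b in range(a, 9)
]


def compute_climate_statistics(
    focal: np.ndarray,
    focal_months: np.ndarray,
    baseline: np.ndarray,
    baseline_months: np.ndarray,
    period: Sequence[int],
    kind: str,
    baseline_years: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Period mean/sum and anomaly rasters from daily weather cubes.

    Temperature: period time-average; anomaly = focal mean − baseline mean
    (°C).  Precipitation: period time-sum; anomaly = 100 × focal sum /
    per-year baseline sum (%).  ``focal``/``baseline`` are (T, rows, cols)
    cubes with per-slice month labels; ``baseline_years`` divides the
    baseline sum into a climatological per-year value.
    """
    period = tuple(period)
    if len(period) == 0:
        raise ValueError("empty period")
    if focal.shape[1:] != baseline.shape[1:]:
        raise ValueError("focal and baseline grids differ")
    if kind not in ("temperature", "precipitation"):
        raise ValueError("kind must be 'temperature' or 'precipitation'")
    fsel = np.isin(focal_months, period)
    bsel = np.isin(baseline_months, period)
    if not fsel.any() or not bsel.any():
        raise ValueError("period not covered by the cubes")
    if kind == "temperature":
        stat = focal[fsel].mean(axis=0)
        anom = stat - baseline[bsel].mean(axis=0)
    else:
        stat = focal[fsel].sum(axis=0)
        base_sum = baseline[bsel].sum(axis=0) / baseline_years
        anom = 100.0 * stat / base_sum
    return stat, anom


# ---------------------------------------------------------------------------
# label polygons (stands in for the visual-interpretation workflow)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelPolygon:
    """A labeled interpretation polygon in scene coordinates."""

    geometry: object  # shapely polygon
    label: str        # presence | absence | artifact
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.label not in ("presence", "absence", "artifact"):
            raise ValueError(f"bad label {self.label!r}")
        if self.geometry.is_empty:
            raise ValueError("empty geometry")


def sample_label_polygons(
    truth: SceneTruth,
    n_presence: int,
    n_absence: int,
    n_artifact: int = 0,
    seed: int = 0,
    half_window: int = 4,
) -> list[LabelPolygon]:
    """Draw label polygons that trace class pixels around random seed pixels.

    Mimics careful visual interpretation: inside the (2·half_window+1)²
    window around each seed pixel, every pixel of the seed's class is
    delineated exactly (union of pixel squares), so each polygon labels a
    homogeneous set of pixels of realistic, variable size.
    """
    from shapely import unary_union

    rng = np.random.default_rng(seed)
    ps = truth.pixel_size
    fmask = truth.forest_mask
    in_mask_grass = fmask & (truth.artifact_class == CLASS_GRASSLAND)
    classes = {
        "presence": truth.labels,
        "absence": fmask & (truth.artifact_class == CLASS_FOREST) & ~truth.labels,
        # interpreters flag the confusable grassland that the mask let through
        "artifact": in_mask_grass if in_mask_grass.any() else ~fmask,
    }
    out: list[LabelPolygon] = []
    for label, n in (("presence", n_presence), ("absence", n_absence), ("artifact", n_artifact)):
        cls = classes[label]
        pool = np.argwhere(cls)
        if n > 0 and len(pool) == 0:
            raise ValueError(f"no pixels available for {label!r} polygons")
        idx = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        for r, c in pool[idx]:
            r0, r1 = max(r - half_window, 0), min(r + half_window + 1, cls.shape[0])
            c0, c1 = max(c - half_window, 0), min(c + half_window + 1, cls.shape[1])
            cells = np.argwhere(cls[r0:r1, c0:c1])
            geom = unary_union(
                [box((c0 + cc) * ps, (r0 + rr) * ps, (c0 + cc + 1) * ps, (r0 + rr + 1) * ps)
                 for rr, cc in cells]
            )
            out.append(LabelPolygon(geom, label))
    return out
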