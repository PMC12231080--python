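"""Synthetic landscape-fire generator.

Everything downstream of the satellite/vegetation archives is exercised on
fires produced here: a patchy categorical vegetation raster, a stochastic
contact-process fire spread whose per-cell daily ignition probability is
scaled down on aspen (the generative truth the statistical pipeline must
recover), thinned and jittered daily detections standing in for
MODIS/VIIRS-style active-fire points, and smooth daily covariate fields
standing in for reanalysis weather grids.

All generators are bit-reproducible given (seed, parameters), with streams
derived per (operation, fire) so adding fires never perturbs existing ones.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage

from .dob import DOBGrid
from .grid import GridSpec, Raster, derive_rng, footprint_polygon
from .landcover import CODE, COVER_TYPES, NODATA, LandcoverGrid

#: Default per-type spread-probability multipliers: aspen is penalized,
#: nonflammable is an absolute barrier, everything else burns at the base
#: rate. These encode the assumed negative aspen effect; the magnitudes are
#: calibration choices, not field measurements.
DEFAULT_MULTIPLIERS: dict[str, float] = {name: 1.0 for name in COVER_TYPES}
DEFAULT_MULTIPLIERS.update({"aspen": 0.3, "nonflammable": 0.0, "prior_burn": 0.5})

_NEIGH8 = np.ones((3, 3), dtype=bool)


@dataclass
class SpreadParams:
    """Parameters of the daily contact-process spread model."""

    base_spread_prob: float = 0.3
    per_type_multiplier: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLIERS)
    )
    weather_coupling: float = 0.0
    max_days: int = 60
    rng_seed: int = 0
    #: ignition generations per day: a front can advance up to this many
    #: cells in one day, all stamped with the same day-of-burning. The
    #: default 1 is one sweep per day; the study conditions use several so
    #: daily progression bands are multiple pixels wide, as they are for
    #: real fires at this grain.
    substeps_per_day: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.base_spread_prob < 1.0 or self.base_spread_prob == 1.0):
            raise ValueError("base_spread_prob must lie in (0, 1]")
        for name, m in self.per_type_multiplier.items():
            if name not in CODE:
                raise ValueError(f"unknown cover type in multiplier map: {name!r}")
            if not (0.0 <= m <= 1.0):
                raise ValueError(f"multiplier for {name!r} outside [0, 1]")

    def multiplier_array(self) -> np.ndarray:
        out = np.array([DEFAULT_MULTIPLIERS[name] for name in COVER_TYPES])
        for name, m in self.per_type_multiplier.items():
            out[CODE[name]] = m
        return out


@dataclass
class Detection:
    """A dated active-fire point in planar meters."""

    x: float
    y: float
    day: int
    sensor: str = "synthetic"

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("detection day indices start at 1")


@dataclass
class FireEvent:
    """A single fire: final perimeter, dated detections, optional truth."""

    fire_id: str
    ignition_date: _dt.date | None
    perimeter: shapely.Geometry
    detections: list[Detection] = field(default_factory=list)
    true_dob: DOBGrid | None = None


def generate_landscape(spec: GridSpec, class_weights: dict[str, float],
                       patchiness: float, seed: int) -> LandcoverGrid:
    """Patchy categorical landscape via a thresholded Gaussian random field.

    A white-noise field is smoothed with a Gaussian kernel of standard
    deviation ``patchiness`` (meters; 0 means independent cells) and split
    into classes at its empirical weight quantiles, so marginal class
    frequencies match ``class_weights`` to within one cell.
    """
    for name in class_weights:
        if name not in CODE:
            raise ValueError(f"unknown cover class in weights: {name!r}")
    names = [n for n in COVER_TYPES if class_weights.get(n, 0.0) > 0]
    weights = np.array([class_weights[n] for n in names], dtype=float)
    if (weights < 0).any():
        raise ValueError("class weights must be nonnegative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("class weights must sum to 1")
    if patchiness < 0:
        raise ValueError("patchiness must be >= 0")

    rng = derive_rng(seed, "landscape")
    fieldvals = rng.standard_normal(spec.shape)
    if patchiness > 0:
        fieldvals = ndimage.gaussian_filter(fieldvals, sigma=patchiness / spec.pixel_size)
    # rank transform -> exact quantile split regardless of smoothing
    order = np.argsort(fieldvals, axis=None, kind="stable")
    ranks = np.empty(spec.n_cells, dtype=np.int64)
    ranks[order] = np.arange(spec.n_cells)
    u = (ranks + 0.5) / spec.n_cells
    edges = np.cumsum(weights)
    idx = np.searchsorted(edges, u.reshape(spec.shape), side="right")
    idx = np.minimum(idx, len(names) - 1)
    classes = np.array([CODE[n] for n in names], dtype=np.int16)[idx]
    return LandcoverGrid(spec, classes)


def simulate_fire(landcover: LandcoverGrid, ignition: tuple[int, int],
                  params: SpreadParams,
                  daily_weather: np.ndarray | list[float] | None = None,
                  fire_id: str = "fire",
                  ignition_date: _dt.date | None = None) -> FireEvent:
    """Daily stochastic contact-process fire spread on the landcover grid.

    Day 1 the ignition cell burns. On each subsequent day every unburned
    cell with at least one burned 8-neighbor ignites with probability

        base_spread_prob * multiplier[cover type] * exp(c * (w_t - w_mean))

    clipped to [0, 1], where c is ``weather_coupling`` and w_t the day's
    weather index. The run stops when no cell ignites or at ``max_days``.
    Returns the final footprint boundary as the perimeter and the per-cell
    ignition day as ground truth.
    """
    spec = landcover.spec
    valid = landcover.classes != landcover.nodata
    if not valid.any():
        raise ValueError("landscape is empty (all nodata)")
    mult = params.multiplier_array()[np.maximum(landcover.classes, 0)]
    mult[~valid] = 0.0

    i0, j0 = ignition
    if not (0 <= i0 < spec.n_rows and 0 <= j0 < spec.n_cols):
        raise ValueError("ignition cell outside grid")
    if mult[i0, j0] <= 0:
        raise ValueError("ignition cell is not flammable")

    weather = np.asarray(daily_weather, dtype=float) if daily_weather is not None else None
    w_mean = float(weather.mean()) if weather is not None and weather.size else 0.0

    rng = derive_rng(params.rng_seed, "simulate", fire_id)
    day_grid = np.zeros(spec.shape, dtype=np.int32)
    day_grid[i0, j0] = 1
    burned = day_grid > 0

    for day in range(2, params.max_days + 1):
        if weather is not None and weather.size:
            w_t = float(weather[min(day - 1, weather.size - 1)])
            factor = float(np.exp(params.weather_coupling * (w_t - w_mean)))
        else:
            factor = 1.0
        prob = np.clip(params.base_spread_prob * mult * factor, 0.0, 1.0)
        any_frontier = False
        for _ in range(max(1, params.substeps_per_day)):
            frontier = ndimage.binary_dilation(burned, structure=_NEIGH8) & ~burned
            if not frontier.any():
                break
            if (prob[frontier] > 0).any():
                any_frontier = True
            ignite = frontier & (rng.random(spec.shape) < prob)
            day_grid[ignite] = day
            burned |= ignite
        if not any_frontier:
            break

    dob = np.where(burned, day_grid, NODATA).astype(np.int32)
    perimeter = footprint_polygon(burned, spec)
    return FireEvent(
        fire_id=fire_id,
        ignition_date=ignition_date,
        perimeter=perimeter,
        detections=[],
        true_dob=DOBGrid(spec, dob),
    )


def sample_detections(true_dob: DOBGrid, rate: float, jitter_sigma: float,
                      seed: int, fire_id: str = "fire",
                      sensor: str = "synthetic",
                      min_per_day: int = 1) -> list[Detection]:
    """Thin each day's newly burned cells into jittered detections.

    ``rate`` is the expected number of detections per 100 burned cells per
    day (independent thinning with retention probability min(1, rate/100));
    retained cells yield a detection at the cell center plus isotropic
    Gaussian positional noise of scale ``jitter_sigma`` meters, carrying the
    true burn day. ``min_per_day`` is an overpass floor: a day with active
    burning is guaranteed that many detections (drawn uniformly from its
    cells) even when thinning would retain none — daily-revisit sensors see
    a front at least once per day. Set it to 0 for pure thinning.
    """
    if rate <= 0:
        raise ValueError("detection rate must be positive")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    day = true_dob.day
    burned = day != true_dob.nodata
    if not burned.any():
        return []
    p_keep = min(1.0, rate / 100.0)
    rng = derive_rng(seed, "detections", fire_id)
    out: list[Detection] = []
    for d in np.unique(day[burned]):
        rows, cols = np.nonzero(day == d)
        keep = rng.random(rows.size) < p_keep
        if keep.sum() < min_per_day:
            forced = rng.choice(rows.size, size=min(min_per_day, rows.size),
                                replace=False)
            keep[forced] = True
        rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            continue
        x, y = true_dob.spec.center_of(rows, cols)
        if jitter_sigma > 0:
            x = x + rng.normal(0.0, jitter_sigma, rows.size)
            y = y + rng.normal(0.0, jitter_sigma, rows.size)
        out.extend(
            Detection(float(xi), float(yi), int(d), sensor) for xi, yi in zip(x, y)
        )
    return out


def generate_covariate_grid(spec: GridSpec, name: str, spatial_scale: float,
                            daily_trend: float, n_days: int,
                            seed: int, fire_id: str = "",
                            day_mean_sd: float = 0.3) -> list[Raster]:
    """Smooth daily covariate fields with a controllable additive trend.

    Each day is an independent unit-variance Gaussian random field smoothed
    at ``spatial_scale`` meters, plus a day-level mean drawn from
    N(0, day_mean_sd^2) — the synoptic component that makes whole days
    hotter or windier than others — plus ``daily_trend * (day - 1)``. The
    covariate name is folded into the random stream, so different covariates
    from the same seed are independent.
    """
    if spatial_scale <= 0:
        raise ValueError("spatial_scale must be positive")
    rng = derive_rng(seed, "covariate", name, fire_id)
    sigma = spatial_scale / spec.pixel_size
    out: list[Raster] = []
    for day in range(1, n_days + 1):
        fieldvals = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=sigma)
        sd = fieldvals.std()
        if sd > 0:
            fieldvals = (fieldvals - fieldvals.mean()) / sd
        day_mean = rng.normal(0.0, day_mean_sd) if day_mean_sd > 0 else 0.0
        out.append(Raster(spec, fieldvals + day_mean + daily_trend * (day - 1)))
    return out
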