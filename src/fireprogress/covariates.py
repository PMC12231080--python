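"""Covariate sampling and transforms: random-pixel sampling of gridded
weather/climate/terrain layers into per-patch means, monthly climate
z-scores, and the circular aspect transform.

Weather-style layers arrive on their own (usually much coarser) grids and
are sampled by nearest-cell lookup at each fine pixel center — no
interpolation — mirroring how a reanalysis cell value is read at a point.
Only 0.1% of a patch's pixels are sampled by default, limiting spatial
autocorrelation among the values averaged into a patch mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import GridSpec, Raster, derive_rng
from .metrics import DOBPatch

#: Covariate names understood by the patch tables; anything else is carried
#: through untouched.
KNOWN_COVARIATES = (
    "AP", "BUI", "DSR", "DC", "DMC", "FFM", "FWI", "ISI", "Tmax", "RH", "WS",
    "CWD_z", "Tmax_z", "VPD_z", "eastness", "northness", "slope", "VRM", "DOY",
)


@dataclass
class ClimateZScore:
    variable: str
    value: float
    ref_mean: float
    ref_sd: float
    z: float


def sample_pixels(pixels: tuple[np.ndarray, np.ndarray], fraction: float = 0.001,
                  seed: int = 0, *tags) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random pixel subset of size max(1, round(fraction * n)).

    Deterministic given (seed, tags); sampling without replacement.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    rows, cols = (np.asarray(p) for p in pixels)
    n = rows.size
    if n == 0:
        raise ValueError("empty pixel set")
    k = max(1, int(round(fraction * n)))
    if k >= n:
        return rows, cols
    rng = derive_rng(seed, "sample_pixels", *tags)
    idx = rng.choice(n, size=k, replace=False)
    return rows[idx], cols[idx]


def patch_covariate_means(patch: DOBPatch, grids: dict[str, Raster | list[Raster]],
                          spec: "GridSpec", fraction: float = 0.001,
                          seed: int = 0) -> dict[str, float]:
    """Mean of each covariate over a random pixel subset of the patch.

    ``grids`` maps a covariate name to either a static raster (terrain) or a
    per-day sequence (daily weather, indexed by patch day, clamped to the
    last available day); ``spec`` is the fine grid the patch pixels index
    into (the DOB grid's spec). The same pixel subset — drawn once per patch
    with a stream keyed by (fire_id, day) — is used for every covariate, as
    in a shared random-point sample. Fills ``patch.covariates`` and returns
    it.
    """
    if not grids:
        raise ValueError("no covariate grids supplied")
    rows, cols = sample_pixels(patch.pixels, fraction, seed, patch.fire_id, patch.day)
    x, y = spec.center_of(rows, cols)
    out: dict[str, float] = {}
    for name, grid in grids.items():
        if isinstance(grid, (list, tuple)):
            if not grid:
                raise ValueError(f"covariate {name!r} has no daily grids")
            raster = grid[min(patch.day - 1, len(grid) - 1)]
        else:
            raster = grid
        out[name] = float(np.mean(raster.sample_nearest(x, y)))
    patch.covariates = out
    return out


def monthly_z(value: float, ref_values) -> ClimateZScore:
    """Standardize a fire-month climate value against a reference sample.

    The reference is the pooled set of April-June monthly values over the
    climatological reference period; sd uses the n-1 denominator. Zero
    reference variance is an error.
    """
    ref = np.asarray(list(ref_values), dtype=float)
    if ref.size < 2:
        raise ValueError("need at least two reference values")
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd <= 0:
        raise ValueError("reference values have zero variance")
    return ClimateZScore("", float(value), mean, sd, (float(value) - mean) / sd)


def aspect_transform(aspect_deg: float) -> tuple[float, float]:
    """Circular aspect (degrees clockwise from north) -> (eastness, northness).

    eastness = sin(aspect), northness = cos(aspect); flat cells (NaN aspect)
    map to (0, 0) by convention.
    """
    if aspect_deg is None or (isinstance(aspect_deg, float) and math.isnan(aspect_deg)):
        return (0.0, 0.0)
    if not (0.0 <= aspect_deg < 360.0):
        raise ValueError("aspect must lie in [0, 360)")
    rad = math.radians(aspect_deg)
    return (math.sin(rad), math.cos(rad))
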