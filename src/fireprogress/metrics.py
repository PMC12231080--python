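"""Daily spread metrics on a day-of-burning grid.

A fire's DOB raster is decomposed into spatially discrete daily patches
(8-connected components of same-day pixels); each patch carries its area in
hectares and its maximum linear spread in meters — the greatest cell
distance from the boundary shared with the previous days' burn, or, for
discontinuous patches (spot fires, first days), from the day's earliest
detection falling inside the patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .dob import DOBGrid
from .synthetic import Detection

_NEIGH8 = np.ones((3, 3), dtype=bool)


@dataclass
class DOBPatch:
    """One connected component of same-day burning."""

    fire_id: str
    day: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    area_ha: float
    max_linear_spread_m: float = np.nan
    min_advance_m: float = np.nan  # alternative closest-boundary statistic
    discontinuous: bool = False
    seed_from_detection: bool = False
    coverage: dict[str, float] | None = None
    covariates: dict[str, float] | None = None

    @property
    def n_pixels(self) -> int:
        return self.pixels[0].size


def daily_area(n_pixels: int, pixel_size: float) -> float:
    """Patch area in hectares: n_pixels * pixel_size^2 / 10,000."""
    return n_pixels * pixel_size ** 2 / 10_000.0


def extract_patches(dob: DOBGrid, fire_id: str = "fire") -> list[DOBPatch]:
    """Split a DOB grid into per-day 8-connected patches.

    Every burned pixel belongs to exactly one patch; patch order is by day,
    then by component label.
    """
    if not dob.burned_mask.any():
        raise ValueError("day-of-burning grid has no burned pixels")
    px = dob.spec.pixel_size
    patches: list[DOBPatch] = []
    for d in dob.days_present():
        labels = measure.label(dob.day == d, connectivity=2)
        for lab in range(1, labels.max() + 1):
            rows, cols = np.nonzero(labels == lab)
            patches.append(
                DOBPatch(
                    fire_id=fire_id,
                    day=int(d),
                    pixels=(rows, cols),
                    area_ha=daily_area(rows.size, px),
                )
            )
    return patches


def shared_boundary(patch: DOBPatch, prior_footprint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Patch pixels 8-adjacent to any pixel burned on an earlier day.

    An empty result marks the patch as discontinuous (no shared boundary
    with the previous days' burn — a spot fire or a first day).
    """
    prior = np.asarray(prior_footprint, dtype=bool)
    rows, cols = patch.pixels
    near_prior = ndimage.binary_dilation(prior, structure=_NEIGH8)
    hit = near_prior[rows, cols]
    return rows[hit], cols[hit]


def max_linear_spread(patch: DOBPatch, prior_footprint: np.ndarray,
                      detections: list[Detection], pixel_size: float,
                      origin_x: float = 0.0, origin_y: float = 0.0) -> DOBPatch:
    """Fill the linear-spread statistics of a patch (in place, returned).

    Continuous patch: for every patch pixel take the Euclidean distance from
    its center to the nearest shared-boundary pixel center; the maximum over
    the patch is the day's linear spread (the value mapped across the whole
    patch). Discontinuous patch: distances are seeded at the day's earliest
    detection falling inside the patch (fallback: the patch centroid).

    ``min_advance_m`` additionally records the minimum distance over the
    patch's non-shared pixels — the closest-boundary reading of daily
    advance — for diagnostics; it does not enter the models.
    """
    rows, cols = patch.pixels
    if rows.size == 0:
        raise ValueError("empty patch")
    x = origin_x + (cols + 0.5) * pixel_size
    y = origin_y - (rows + 0.5) * pixel_size
    pts = np.column_stack([x, y])

    b_rows, b_cols = shared_boundary(patch, prior_footprint)
    if b_rows.size > 0:
        patch.discontinuous = False
        bx = origin_x + (b_cols + 0.5) * pixel_size
        by = origin_y - (b_rows + 0.5) * pixel_size
        dist, _ = cKDTree(np.column_stack([bx, by])).query(pts, k=1)
        patch.max_linear_spread_m = float(dist.max())
        nonshared = dist > 0
        patch.min_advance_m = float(dist[nonshared].min()) if nonshared.any() else 0.0
        return patch

    patch.discontinuous = True
    seed = _patch_seed_point(patch, detections, pixel_size, origin_x, origin_y)
    if seed is None:
        seed = (float(x.mean()), float(y.mean()))
        patch.seed_from_detection = False
    else:
        patch.seed_from_detection = True
    dist = np.hypot(pts[:, 0] - seed[0], pts[:, 1] - seed[1])
    patch.max_linear_spread_m = float(dist.max())
    patch.min_advance_m = float(dist[dist > 0].min()) if (dist > 0).any() else 0.0
    return patch


def _patch_seed_point(patch, detections, pixel_size, origin_x, origin_y):
    """First same-day detection whose cell falls inside the patch, if any."""
    cells = set(zip(patch.pixels[0].tolist(), patch.pixels[1].tolist()))
    for det in detections:
        if int(det.day) != patch.day:
            continue
        col = int(np.floor((det.x - origin_x) / pixel_size))
        row = int(np.floor((origin_y - det.y) / pixel_size))
        if (row, col) in cells:
            return (float(det.x), float(det.y))
    return None


def compute_spread_metrics(dob: DOBGrid, detections: list[Detection],
                           fire_id: str = "fire") -> list[DOBPatch]:
    """Extract all daily patches and fill their linear-spread metrics.

    The prior footprint for a day's patches is the set of pixels burned on
    any strictly earlier day.
    """
    spec = dob.spec
    patches = extract_patches(dob, fire_id)
    for patch in patches:
        prior = dob.burned_mask & (dob.day < patch.day)
        max_linear_spread(patch, prior, detections, spec.pixel_size,
                          spec.origin_x, spec.origin_y)
    return patches
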