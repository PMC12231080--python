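"""Day-of-burning (DOB) interpolation from dated fire detections.

Each pixel inside a fire's final perimeter is assigned the burn day of its
nearest dated detection (planar Euclidean distance from pixel center to
detection point), ties going to the earlier day. This is the simplest member
of the detection-interpolation family used for satellite fire-progression
mapping, pinned here for reproducibility; the function signature leaves room
for k-NN/IDW variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree

from .grid import GridSpec, rasterize_polygon
from .landcover import CODE, LandcoverGrid

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import FireEvent

NODATA_DAY = -1
_TIE_TOL = 1e-9


@dataclass
class DOBGrid:
    """Integer day-of-burning raster; nodata outside the burned area."""

    spec: GridSpec
    day: np.ndarray
    nodata: int = NODATA_DAY

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=np.int32)
        if self.day.shape != self.spec.shape:
            raise ValueError("day raster shape does not match grid spec")
        burned = self.day != self.nodata
        if burned.any() and (self.day[burned] < 1).any():
            raise ValueError("burn days must be >= 1")

    @property
    def burned_mask(self) -> np.ndarray:
        return self.day != self.nodata

    def days_present(self) -> np.ndarray:
        m = self.burned_mask
        return np.unique(self.day[m]) if m.any() else np.array([], dtype=np.int32)


def interpolate_dob(fire: "FireEvent", spec: GridSpec) -> DOBGrid:
    """Nearest-detection day assignment inside the final perimeter.

    Detections outside the perimeter still contribute to the interpolation
    but generate no pixels of their own; distance ties are resolved to the
    earlier day; the output only contains days present among detections.
    """
    if not fire.detections:
        raise ValueError("cannot interpolate day of burning without detections")
    inside = rasterize_polygon(fire.perimeter, spec)
    day = np.full(spec.shape, NODATA_DAY, dtype=np.int32)
    if not inside.any():
        return DOBGrid(spec, day)

    rows, cols = np.nonzero(inside)
    px, py = spec.center_of(rows, cols)
    pts = np.column_stack([px, py])

    by_day: dict[int, list[tuple[float, float]]] = {}
    for det in fire.detections:
        by_day.setdefault(int(det.day), []).append((det.x, det.y))

    best = np.full(rows.size, np.inf)
    assigned = np.full(rows.size, NODATA_DAY, dtype=np.int32)
    for d in sorted(by_day):  # ascending: earlier day wins exact ties
        tree = cKDTree(np.asarray(by_day[d]))
        dist, _ = tree.query(pts, k=1)
        better = dist < best - _TIE_TOL
        best[better] = dist[better]
        assigned[better] = d
    day[rows, cols] = assigned
    return DOBGrid(spec, day)


def passes_inclusion_filters(fire: "FireEvent", landcover: LandcoverGrid,
                             min_detections: int = 10,
                             min_aspen_fraction: float = 0.001) -> tuple[bool, list[str]]:
    """Fire-inclusion filters: enough detections and some aspen present.

    A fire enters the spread analysis only if it has at least
    ``min_detections`` detections and the rasterized perimeter contains at
    least ``min_aspen_fraction`` aspen (both bounds inclusive). Returns the
    flag plus the list of failed filters ("detections", "aspen").
    """
    reasons: list[str] = []
    if len(fire.detections) < min_detections:
        reasons.append("detections")
    inside = rasterize_polygon(fire.perimeter, landcover.spec)
    sel = inside & (landcover.classes != landcover.nodata)
    if not sel.any():
        reasons.append("aspen")
    else:
        aspen_frac = float((landcover.classes[sel] == CODE["aspen"]).mean())
        if aspen_frac < min_aspen_fraction:
            reasons.append("aspen")
    return (not reasons), reasons


def dob_agreement(interp: DOBGrid, truth: DOBGrid, within_days: int = 1) -> float:
    """Fraction of commonly burned pixels whose days agree within a slack.

    Used as a regression guard for the interpolation under realistic
    detection thinning and positional jitter.
    """
    common = interp.burned_mask & truth.burned_mask
    if not common.any():
        raise ValueError("no commonly burned pixels to compare")
    diff = np.abs(interp.day[common] - truth.day[common])
    return float((diff <= within_days).mean())
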