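"""Fire Perimeter Effect (FPE): cover-type abundance at fire perimeters
versus burn interiors.

For a cover type with proportion P in a 120-m band straddling the final
perimeter (60 m on either side) and proportion I in the burn interior,

    FPE = (P - I) / (P + I),

a scale-independent statistic in [-1, 1]; positive values mean the type is
over-represented where the fire stopped (a barrier effect). Per type, the
per-fire FPE signs are tested with an exact two-sided binomial sign test at
a Bonferroni-adjusted threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import stats

from .grid import GridSpec
from .landcover import COVER_TYPES, LandcoverGrid, cover_proportions


@dataclass
class FPERecord:
    fire_id: str
    group: str
    perimeter_prop: float
    interior_prop: float
    fpe: float  # NaN when both proportions are zero (undefined)


@dataclass
class SignTestResult:
    group: str
    n_pos: int
    n_neg: int
    n_excluded: int
    p_value: float  # NaN when no informative fires
    significant: bool


def perimeter_interior_masks(perimeter: shapely.Geometry, spec: GridSpec,
                             half_width: float = 60.0,
                             interior_mode: str = "full",
                             ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Boolean cell masks for the perimeter band and the burn interior.

    Perimeter band: cells whose centers lie within ``half_width`` meters of
    the perimeter line, on either side (a 2*half_width-wide band capturing
    vegetation that was burned over at the fire's edge as well as unburned
    vegetation just outside it). Interior: cells inside the polygon farther
    than ``half_width`` from the boundary — the whole deep burn by default
    (``interior_mode="full"``), or only a ``half_width``-wide inner ring
    hugging the band (``interior_mode="ring"``). The two sets are disjoint.

    Returns (perimeter_mask, interior_mask, interior_empty_flag).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if interior_mode not in ("full", "ring"):
        raise ValueError("interior_mode must be 'full' or 'ring'")
    boundary = perimeter.boundary
    X, Y = spec.center_meshgrid()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = shapely.distance(boundary, pts).reshape(spec.shape)
    inside = shapely.contains_xy(perimeter, X.ravel(), Y.ravel()).reshape(spec.shape)

    perim = dist <= half_width
    interior = inside & (dist > half_width)
    if interior_mode == "ring":
        interior &= dist <= 2 * half_width
    return perim, interior, not interior.any()


def fpe(perimeter_prop: float, interior_prop: float) -> float:
    """(P - I) / (P + I); NaN when P + I = 0 (type absent from both)."""
    for v in (perimeter_prop, interior_prop):
        if not (0.0 <= v <= 1.0):
            raise ValueError("proportions must lie in [0, 1]")
    total = perimeter_prop + interior_prop
    if total == 0:
        return math.nan
    return (perimeter_prop - interior_prop) / total


def implied_abundance_excess(fpe_value: float) -> float:
    """Percent by which perimeter abundance exceeds interior abundance.

    Inverts the FPE: P/I = (1 + FPE)/(1 - FPE), so the excess is
    100 * ((1 + FPE)/(1 - FPE) - 1). Undefined at |FPE| = 1.
    """
    if abs(fpe_value) >= 1.0:
        raise ValueError("abundance ratio is infinite at |FPE| = 1")
    return 100.0 * ((1.0 + fpe_value) / (1.0 - fpe_value) - 1.0)


def bonferroni_threshold(alpha: float = 0.05, k: int = 11) -> float:
    """Per-test significance threshold controlling family-wise error."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def sign_test(fpe_values, group: str = "", alpha_threshold: float = 0.05 / 11) -> SignTestResult:
    """Exact two-sided binomial sign test on per-fire FPE signs.

    Undefined (NaN) and exactly-zero values are excluded (counted in
    ``n_excluded``); the p-value is the minimum-likelihood two-sided exact
    binomial probability of the (n_pos, n_pos + n_neg) split at null success
    probability 0.5. With no informative values the p-value is NaN.
    """
    vals = np.asarray(list(fpe_values), dtype=float)
    finite = vals[np.isfinite(vals)]
    n_pos = int((finite > 0).sum())
    n_neg = int((finite < 0).sum())
    n_excl = int(vals.size - n_pos - n_neg)
    n = n_pos + n_neg
    if n == 0:
        return SignTestResult(group, 0, 0, n_excl, math.nan, False)
    p = float(stats.binomtest(n_pos, n, 0.5, alternative="two-sided").pvalue)
    return SignTestResult(group, n_pos, n_neg, n_excl, p, p < alpha_threshold)


def fpe_records_for_fire(fire_id: str, perimeter: shapely.Geometry,
                         landcover: LandcoverGrid, half_width: float = 60.0,
                         interior_mode: str = "full") -> list[FPERecord]:
    """Per-cover-type FPE records for one fire."""
    perim_mask, int_mask, empty = perimeter_interior_masks(
        perimeter, landcover.spec, half_width, interior_mode
    )
    if empty:
        raise ValueError(f"fire {fire_id!r}: no interior at half_width={half_width}")
    p_props = cover_proportions(landcover, np.nonzero(perim_mask)).proportions
    i_props = cover_proportions(landcover, np.nonzero(int_mask)).proportions
    return [
        FPERecord(fire_id, g, p_props[g], i_props[g], fpe(p_props[g], i_props[g]))
        for g in COVER_TYPES
    ]


def sign_tests_by_group(records: list[FPERecord], alpha: float = 0.05,
                        k: int | None = None) -> list[SignTestResult]:
    """One sign test per cover group at the Bonferroni-adjusted threshold."""
    groups = sorted({r.group for r in records}, key=COVER_TYPES.index)
    threshold = bonferroni_threshold(alpha, k if k is not None else len(groups))
    out = []
    for g in groups:
        vals = [r.fpe for r in records if r.group == g]
        out.append(sign_test(vals, group=g, alpha_threshold=threshold))
    return out
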