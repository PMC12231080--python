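"""Coarse vegetation classification: legend reclassification, prior-burn
overlay, and cover-type proportions over arbitrary pixel sets.

Fine existing-vegetation-type (EVT) legends are collapsed to 11 coarse
groups; areas burned 1-10 years before a focal fire are reclassified as
``prior_burn`` because recent burns impede subsequent spread.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .grid import GridSpec, rasterize_polygon

#: The 11 coarse cover groups. ``prior_burn`` is assigned from fire history,
#: the other 10 from the vegetation legend.
COVER_TYPES: tuple[str, ...] = (
    "aspen",
    "cool_conifer",
    "disturbed",
    "herbaceous",
    "mixed_aspen_conifer",
    "nonflammable",
    "shrub",
    "warm_conifer",
    "wetland",
    "woodland",
    "prior_burn",
)

CODE: dict[str, int] = {name: i for i, name in enumerate(COVER_TYPES)}
NODATA: int = -1


@dataclass
class LandcoverGrid:
    """Categorical raster over the 11-group vocabulary (integer codes)."""

    spec: GridSpec
    classes: np.ndarray
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        if self.classes.shape != self.spec.shape:
            raise ValueError("class raster shape does not match grid spec")
        valid = (self.classes == self.nodata) | (
            (self.classes >= 0) & (self.classes < len(COVER_TYPES))
        )
        if not valid.all():
            bad = np.unique(self.classes[~valid])
            raise ValueError(f"class codes outside the 11-group vocabulary: {bad.tolist()}")

    def mask_of(self, group: str) -> np.ndarray:
        return self.classes == CODE[group]

    def copy(self) -> "LandcoverGrid":
        return LandcoverGrid(self.spec, self.classes.copy(), self.nodata)


@dataclass
class LegendMapping:
    """Total map from fine legend codes to coarse group names."""

    entries: dict[int, str]

    def __post_init__(self) -> None:
        bad = sorted({g for g in self.entries.values() if g not in CODE})
        if bad:
            raise ValueError(f"mapping targets are not valid cover groups: {bad}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LegendMapping":
        """Read a two-column ``fine_code,group`` CSV (header optional)."""
        entries: dict[int, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("fine_code", ""):
                    continue
                entries[int(row[0])] = row[1].strip()
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fine_code", "group"])
            for code in sorted(self.entries):
                w.writerow([code, self.entries[code]])


@dataclass
class BurnHistory:
    """Prior fire perimeters with their calendar years."""

    records: list[tuple[shapely.Geometry, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, year in self.records:
            if int(year) <= 0:
                raise ValueError("burn years must be positive integers")


@dataclass
class CoverProportions:
    proportions: dict[str, float]
    n_pixels: int


def reclassify(fine_raster: np.ndarray, mapping: LegendMapping, spec: GridSpec,
               nodata: int = NODATA) -> LandcoverGrid:
    """Collapse a fine-code integer raster to the 11 coarse groups.

    Every non-nodata code present must be covered by the mapping; unmapped
    codes raise with the offending code list.
    """
    fine = np.asarray(fine_raster)
    present = np.unique(fine[fine != nodata])
    missing = sorted(int(c) for c in present if int(c) not in mapping.entries)
    if missing:
        raise ValueError(f"legend mapping does not cover fine codes: {missing}")
    out = np.full(fine.shape, nodata, dtype=np.int16)
    for code in present:
        out[fine == code] = CODE[mapping.entries[int(code)]]
    return LandcoverGrid(spec, out, nodata)


def apply_prior_burns(landcover: LandcoverGrid, history: BurnHistory,
                      fire_year: int) -> LandcoverGrid:
    """Overlay ``prior_burn`` for areas burned 1-10 years before the fire.

    The most recent prior burn at each cell decides its burn-year gap
    (overlapping perimeters: later burn takes precedence); cells whose gap
    falls in [1, 10] become ``prior_burn``, all others are unchanged.
    Idempotent for fixed (history, fire_year).
    """
    years = [y for _, y in history.records]
    if years and fire_year < max(years):
        raise ValueError("fire_year precedes a burn in the history")
    last_burn = np.zeros(landcover.spec.shape, dtype=np.int32)
    for geom, year in history.records:
        inside = rasterize_polygon(geom, landcover.spec)
        np.maximum(last_burn, np.where(inside, int(year), 0), out=last_burn)
    gap = fire_year - last_burn
    out = landcover.copy()
    hit = (last_burn > 0) & (gap >= 1) & (gap <= 10) & (out.classes != landcover.nodata)
    out.classes[hit] = CODE["prior_burn"]
    return out


def cover_proportions(landcover: LandcoverGrid,
                      pixels: tuple[np.ndarray, np.ndarray]) -> CoverProportions:
    """Proportions of the 11 groups over exactly the given (rows, cols) set.

    Nodata cells are dropped before normalizing; an empty or all-nodata
    pixel set is an error.
    """
    rows, cols = (np.asarray(p) for p in pixels)
    if rows.size == 0:
        raise ValueError("empty pixel set")
    if (rows < 0).any() or (rows >= landcover.spec.n_rows).any() \
            or (cols < 0).any() or (cols >= landcover.spec.n_cols).any():
        raise ValueError("pixel indices outside grid")
    vals = landcover.classes[rows, cols]
    vals = vals[vals != landcover.nodata]
    if vals.size == 0:
        raise ValueError("pixel set contains only nodata cells")
    counts = np.bincount(vals, minlength=len(COVER_TYPES))
    props = counts / vals.size
    return CoverProportions(
        proportions={name: float(props[CODE[name]]) for name in COVER_TYPES},
        n_pixels=int(vals.size),
    )


def load_stub_legend() -> LegendMapping:
    """The bundled synthetic 20-code stub legend.

    A stand-in for a real fine-vegetation crosswalk (which is data the user
    supplies as a two-column CSV); useful for demos and tests.
    """
    from importlib import resources

    path = resources.files("fireprogress") / "data" / "evt_legend_stub_synthetic.csv"
    with resources.as_file(path) as p:
        return LegendMapping.from_csv(p)


def select_evt_version(versions: dict[int, LandcoverGrid], fire_year: int) -> LandcoverGrid:
    """Pick the vegetation-layer version for a fire year.

    Uses the most recent version year strictly preceding the fire year
    (version_year <= fire_year - 1), falling back to the earliest version
    when the fire predates them all.
    """
    if not versions:
        raise ValueError("no landcover versions supplied")
    eligible = [y for y in versions if y <= fire_year - 1]
    year = max(eligible) if eligible else min(versions)
    return versions[year]
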