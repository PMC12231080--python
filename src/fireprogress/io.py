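"""Plain-text file formats for every stage artifact.

Rasters are exchanged as ESRI ASCII grids (single band, nodata-aware,
GDAL-readable), perimeters and burn histories as GeoJSON, detections and
patch tables as CSV — so any stage of a run can be inspected or re-entered
with ordinary tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grid import GridSpec, Raster
from .landcover import COVER_TYPES, BurnHistory, LandcoverGrid
from .metrics import DOBPatch
from .dob import DOBGrid
from .synthetic import Detection


def write_ascii_grid(raster: Raster | LandcoverGrid | DOBGrid, path: str | Path,
                     fmt: str = "%.6g") -> None:
    spec = raster.spec
    if isinstance(raster, LandcoverGrid):
        values, nodata = raster.classes, raster.nodata
        fmt = "%d"
    elif isinstance(raster, DOBGrid):
        values, nodata = raster.day, raster.nodata
        fmt = "%d"
    else:
        values, nodata = raster.values, raster.nodata
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.pixel_size!r}\n"
        f"cellsize {spec.pixel_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def read_ascii_grid(path: str | Path, dtype=float) -> Raster:
    with open(path) as fh:
        hdr: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=dtype, ndmin=2)
    n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
    px = hdr["cellsize"]
    spec = GridSpec(
        n_rows, n_cols, px,
        origin_x=hdr["xllcorner"],
        origin_y=hdr["yllcorner"] + n_rows * px,
    )
    return Raster(spec, values, nodata=dtype(hdr["nodata_value"]))


def read_landcover(path: str | Path) -> LandcoverGrid:
    r = read_ascii_grid(path, dtype=int)
    return LandcoverGrid(r.spec, r.values.astype(np.int16), nodata=int(r.nodata))


def read_dob(path: str | Path) -> DOBGrid:
    r = read_ascii_grid(path, dtype=int)
    return DOBGrid(r.spec, r.values, nodata=int(r.nodata))


def write_perimeter_geojson(geom: shapely.Geometry, path: str | Path,
                            properties: dict | None = None) -> None:
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": mapping(geom),
    }
    doc = {"type": "FeatureCollection", "features": [feature]}
    Path(path).write_text(json.dumps(doc))


def read_perimeter_geojson(path: str | Path) -> tuple[shapely.Geometry, dict]:
    doc = json.loads(Path(path).read_text())
    feat = doc["features"][0]
    return shape(feat["geometry"]), feat.get("properties", {})


def write_burn_history_geojson(history: BurnHistory, path: str | Path) -> None:
    feats = [
        {"type": "Feature", "properties": {"year": int(year)}, "geometry": mapping(geom)}
        for geom, year in history.records
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_burn_history_geojson(path: str | Path) -> BurnHistory:
    doc = json.loads(Path(path).read_text())
    records = [
        (shape(f["geometry"]), int(f["properties"]["year"])) for f in doc["features"]
    ]
    return BurnHistory(records)


def write_detections_csv(detections: list[Detection], fire_id: str,
                         path: str | Path) -> None:
    df = pd.DataFrame(
        [{"fire_id": fire_id, "x": d.x, "y": d.y, "day": d.day, "sensor": d.sensor}
         for d in detections]
    )
    if df.empty:
        df = pd.DataFrame(columns=["fire_id", "x", "y", "day", "sensor"])
    df.to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> dict[str, list[Detection]]:
    df = pd.read_csv(path)
    out: dict[str, list[Detection]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.fire_id), []).append(
            Detection(float(row.x), float(row.y), int(row.day), str(row.sensor))
        )
    return out


def patch_table(patches: list[DOBPatch]) -> pd.DataFrame:
    """Flatten patches (with coverage and covariate means) into a table.

    One row per patch: fire_id, day, n_pixels, area_ha, max_linear_spread_m,
    discontinuous, one column per cover type proportion, one per covariate.
    """
    rows = []
    for p in patches:
        row = {
            "fire_id": p.fire_id,
            "day": p.day,
            "n_pixels": p.n_pixels,
            "area_ha": p.area_ha,
            "max_linear_spread_m": p.max_linear_spread_m,
            "min_advance_m": p.min_advance_m,
            "discontinuous": p.discontinuous,
            "seed_from_detection": p.seed_from_detection,
        }
        for g in COVER_TYPES:
            row[g] = (p.coverage or {}).get(g, np.nan)
        for name, val in (p.covariates or {}).items():
            row[name] = val
        rows.append(row)
    return pd.DataFrame(rows)
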