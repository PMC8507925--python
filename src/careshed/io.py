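"""GeoJSON and raster input/output.

Geometries travel as GeoJSON (plain JSON handled with ``shapely``); rasters as
single-band TIFF with GeoTIFF pixel-scale/tiepoint tags plus an ESRI world
file (``.tfw``) sidecar, written and read via ``tifffile``. All coordinates
must be in one projected CRS in metres; files whose coordinates look like
longitude/latitude degrees are refused.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any, Iterable

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

_GEOGRAPHIC_CRS_HINTS = ("4326", "crs84", "wgs 84", "wgs84")


class CRSError(ValueError):
    """Raised when inputs are in a geographic (degree-based) or mixed CRS."""


def _crs_tag_of(doc: dict) -> str:
    crs = doc.get("crs")
    if isinstance(crs, dict):
        name = str(crs.get("properties", {}).get("name", ""))
        if name:
            return name
    return "unspecified-projected"


def _reject_geographic(crs_tag: str, coords_bounds: tuple[float, float, float, float], path: str) -> None:
    low = crs_tag.lower()
    if any(h in low for h in _GEOGRAPHIC_CRS_HINTS):
        raise CRSError(
            f"{path}: CRS {crs_tag!r} is geographic (degrees); a projected CRS in metres is required"
        )
    minx, miny, maxx, maxy = coords_bounds
    if crs_tag == "unspecified-projected" and (
        -180 <= minx <= maxx <= 180 and -90 <= miny <= maxy <= 90
    ):
        raise CRSError(
            f"{path}: coordinates fall inside longitude/latitude bounds and no projected "
            "CRS is declared; refusing degree-based input"
        )


def read_geojson(path: str | os.PathLike) -> tuple[list[tuple[BaseGeometry, dict]], str]:
    """Read a GeoJSON file into (geometry, properties) pairs.

    Returns the features and the CRS tag. Rejects inputs that appear to be in
    a geographic CRS (see module docstring).
    """
    with open(path) as fh:
        doc = json.load(fh)
    crs_tag = _crs_tag_of(doc)
    if doc.get("type") == "FeatureCollection":
        raw = doc.get("features", [])
    elif doc.get("type") == "Feature":
        raw = [doc]
    else:  # bare geometry
        raw = [{"type": "Feature", "geometry": doc, "properties": {}}]
    feats = [(shape(f["geometry"]), f.get("properties") or {}) for f in raw if f.get("geometry")]
    if feats:
        bounds = np.array([g.bounds for g, _ in feats])
        total = (bounds[:, 0].min(), bounds[:, 1].min(), bounds[:, 2].max(), bounds[:, 3].max())
        _reject_geographic(crs_tag, total, str(path))
    return feats, crs_tag


def write_geojson(
    path: str | os.PathLike,
    features: Iterable[tuple[BaseGeometry, dict]],
    crs_tag: str | None = None,
) -> None:
    doc: dict[str, Any] = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    if crs_tag and crs_tag != "unspecified-projected":
        doc["crs"] = {"type": "name", "properties": {"name": crs_tag}}
    with open(path, "w") as fh:
        json.dump(doc, fh, separators=(",", ":"))
        fh.write("\n")


def write_raster(
    path: str | os.PathLike,
    values: np.ndarray,
    origin_x: float,
    origin_y: float,
    cell_size: float,
    nodata: float = -1.0,
) -> None:
    """Write a south-up grid (row 0 = southernmost) as a georeferenced TIFF.

    ``origin_x, origin_y`` are the coordinates of the grid's south-west
    corner. NaNs are stored as ``nodata``. A ``.tfw`` world file is written
    alongside, and GeoTIFF ModelPixelScale/ModelTiepoint tags are embedded.
    """
    nrows = values.shape[0]
    out = np.where(np.isnan(values), nodata, values).astype(np.float32)
    out = out[::-1]  # TIFF row 0 is northernmost
    top_y = origin_y + nrows * cell_size
    extratags = [
        # ModelPixelScaleTag, ModelTiepointTag: raster-to-world transform
        (33550, "d", 3, (cell_size, cell_size, 0.0), True),
        (33922, "d", 6, (0.0, 0.0, 0.0, origin_x, top_y, 0.0), True),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
    tfw = os.fspath(path)
    tfw = tfw[: tfw.rfind(".")] + ".tfw" if "." in os.path.basename(tfw) else tfw + ".tfw"
    with open(tfw, "w") as fh:
        # world file: pixel sizes, rotations, centre of the upper-left pixel
        fh.write(
            f"{cell_size}\n0.0\n0.0\n{-cell_size}\n"
            f"{origin_x + cell_size / 2}\n{top_y - cell_size / 2}\n"
        )


def read_raster(path: str | os.PathLike) -> tuple[np.ndarray, float, float, float, float]:
    """Read a single-band TIFF; returns (south-up values, origin_x, origin_y, cell_size, nodata).

    Georeferencing is taken from GeoTIFF tags when present, else from a
    ``.tfw`` world file next to the raster.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    nrows = arr.shape[0]
    if 33550 in tags and 33922 in tags:
        sx, sy = float(tags[33550][0]), float(tags[33550][1])
        tp = tags[33922]
        origin_x = float(tp[3])
        top_y = float(tp[4])
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square pixels are not supported")
        cell = sx
    else:
        tfw = os.fspath(path)
        tfw = tfw[: tfw.rfind(".")] + ".tfw"
        if not os.path.exists(tfw):
            raise ValueError(f"{path}: no GeoTIFF tags and no {tfw} world file; raster is not georeferenced")
        with open(tfw) as fh:
            a, d, b, e, cx, cy = (float(line) for line in fh.read().split())
        if d != 0 or b != 0:
            raise ValueError(f"{path}: rotated rasters are not supported")
        if abs(a + e) > 1e-9:
            raise ValueError(f"{path}: non-square pixels are not supported")
        cell = a
        origin_x = cx - cell / 2
        top_y = cy + cell / 2
    origin_y = top_y - nrows * cell
    values = arr[::-1]  # back to south-up
    nodata = -1.0
    values = np.where(values == nodata, np.nan, values)
    if not math.isfinite(cell) or cell <= 0:
        raise ValueError(f"{path}: invalid cell size {cell}")
    return values, origin_x, origin_y, cell, nodata
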