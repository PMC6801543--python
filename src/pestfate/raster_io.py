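"""GeoTIFF-style raster I/O.

Grids are written as TIFF files carrying the standard GeoTIFF
georeferencing tags (ModelPixelScale 33550, ModelTiepoint 33922), the
GDAL nodata tag (42113) and a JSON ImageDescription with units, CRS tag
and process metadata.  Multi-band stacks (e.g. 12 monthly climate
grids) are written as one multi-page file.  No reprojection or implicit
resampling is ever performed on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import Grid, GridStack

__all__ = ["write_grid", "read_grid", "write_stack", "read_stack"]

NODATA = -9999.0

_PIXELSCALE = 33550
_TIEPOINT = 33922
_GDAL_NODATA = 42113


def _geo_extratags(g: Grid, meta: dict) -> list:
    x0, dx, _, y0, _, dy = g.transform
    return [
        (_PIXELSCALE, "d", 3, (dx, -dy, 0.0)),
        (_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_GDAL_NODATA, "s", 0, str(NODATA)),
    ]


def write_grid(path: str | Path, g: Grid, process: str = "",
               extra_meta: dict | None = None) -> Path:
    """Write one Grid as a single-band float TIFF with geo tags."""
    path = Path(path)
    meta = {"units": g.units, "crs_tag": g.crs_tag, "nodata": NODATA}
    if process:
        meta["process"] = process
    if extra_meta:
        meta.update(extra_meta)
    data = g.filled(NODATA).astype(np.float64)
    tifffile.imwrite(path, data, description=json.dumps(meta),
                     metadata=None, extratags=_geo_extratags(g, meta))
    return path


def _parse_page(page) -> tuple[tuple[float, ...], float, dict]:
    tags = {t.code: t.value for t in page.tags.values()}
    if _PIXELSCALE in tags and _TIEPOINT in tags:
        dx, dy, _ = tags[_PIXELSCALE]
        _, _, _, x0, y0, _ = tags[_TIEPOINT]
        transform = (float(x0), float(dx), 0.0, float(y0), 0.0, -float(dy))
    else:
        transform = (0.0, 1.0, 0.0, float(page.shape[0]), 0.0, -1.0)
    nodata = float(tags.get(_GDAL_NODATA, NODATA))
    desc = tags.get(270, "")
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    return transform, nodata, meta


def read_grid(path: str | Path) -> Grid:
    """Read a single-band TIFF back into a Grid (nodata tag honored)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        transform, nodata, meta = _parse_page(page)
        data = page.asarray().astype(float)
    mask = (data == nodata) | ~np.isfinite(data)
    return Grid(np.where(mask, np.nan, data), transform, mask,
                units=meta.get("units", ""),
                crs_tag=meta.get("crs_tag", "local-metric"))


def write_stack(path: str | Path, stack: GridStack,
                extra_meta: dict | None = None) -> Path:
    """Write a (temporal) stack as a multi-page TIFF, one band per key."""
    path = Path(path)
    keys = sorted(stack.grids)
    ref = stack[keys[0]]
    meta = {"units": ref.units, "crs_tag": ref.crs_tag, "nodata": NODATA,
            "bands": [str(k) for k in keys], "temporal": stack.temporal}
    if extra_meta:
        meta.update(extra_meta)
    data = np.stack([stack[k].filled(NODATA) for k in keys]).astype(np.float64)
    tifffile.imwrite(path, data, description=json.dumps(meta),
                     metadata=None, extratags=_geo_extratags(ref, meta))
    return path


def read_stack(path: str | Path) -> GridStack:
    """Read a multi-page TIFF into a GridStack (12 pages → months 1..12)."""
    with tifffile.TiffFile(path) as tif:
        transform, nodata, meta = _parse_page(tif.pages[0])
        data = tif.asarray().astype(float)
    if data.ndim == 2:
        data = data[None]
    temporal = bool(meta.get("temporal", data.shape[0] == 12))
    band_names = meta.get("bands")
    grids = {}
    for i in range(data.shape[0]):
        band = data[i]
        mask = (band == nodata) | ~np.isfinite(band)
        if temporal:
            key: object = i + 1
        else:
            key = band_names[i] if band_names else str(i)
        grids[key] = Grid(np.where(mask, np.nan, band), transform, mask,
                          units=meta.get("units", ""),
                          crs_tag=meta.get("crs_tag", "local-metric"))
    return GridStack(grids, temporal=temporal)
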