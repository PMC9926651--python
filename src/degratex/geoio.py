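"""Reading and writing rasters and reference polygons.

Rasters travel as TIFF files with the grid metadata (pixel size, origin,
nodata, band names) serialised as JSON in the ImageDescription tag, so a
write/read round trip is lossless. Reference polygons travel as GeoJSON
FeatureCollections whose features carry ``dclass`` and ``event_year``
properties; geometries are in raster (col, row) coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

from .raster import Raster

__all__ = ["read_raster", "write_raster", "read_polygons", "write_polygons"]

_FLOAT_NODATA = float("nan")
_INT_NODATA = -9999


def write_raster(path: str | Path, raster: Raster) -> Path:
    """Write a Raster (2-D or band-stacked 3-D) to a TIFF file."""
    path = Path(path)
    data = raster.data
    if np.issubdtype(data.dtype, np.floating):
        out = data.astype(np.float64, copy=True)
        out[raster.mask] = _FLOAT_NODATA
        nodata = "nan"
    else:
        out = data.astype(np.int32, copy=True)
        out[raster.mask] = _INT_NODATA
        nodata = _INT_NODATA
    desc = json.dumps(
        {
            "pixel_size": raster.pixel_size,
            "origin": list(raster.origin),
            "nodata": nodata,
            "meta": raster.meta,
        }
    )
    kwargs = {"photometric": "minisblack"}
    if out.ndim == 3:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(path, out, description=desc, **kwargs)
    return path


def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise ValueError(f"cannot parse raster file {path}: {exc}") from exc
    info = json.loads(desc) if desc else {}
    nodata = info.get("nodata", "nan")
    if np.issubdtype(data.dtype, np.floating):
        mask = ~np.isfinite(data)
    else:
        mask = data == nodata
    return Raster(
        data,
        mask,
        pixel_size=float(info.get("pixel_size", 1.0)),
        origin=tuple(info.get("origin", (0.0, 0.0))),
        meta=info.get("meta", {}),
    )


def write_polygons(path: str | Path, polygons) -> Path:
    """Write ReferencePolygon-like objects as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {"dclass": p.dclass, "event_year": p.event_year},
        }
        for p in polygons
    ]
    payload = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(payload))
    return path


def read_polygons(path: str | Path):
    from .landscape import ReferencePolygon  # local import avoids cycle

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        features = payload["features"]
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse GeoJSON file {path}: {exc}") from exc
    out = []
    for feat in features:
        props = feat.get("properties", {})
        out.append(
            ReferencePolygon(
                geometry=shape(feat["geometry"]),
                dclass=props["dclass"],
                event_year=int(props["event_year"]),
            )
        )
    return out
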