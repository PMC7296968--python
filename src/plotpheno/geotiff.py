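"""GeoTIFF reading/writing for the small subset of the format the pipeline uses.

North-up rasters only, georeferenced with the standard ModelPixelScale +
ModelTiepoint tag pair; an EPSG code travels in the GeoKeyDirectory and the
nodata sentinel in the GDAL_NODATA ASCII tag. Multiband stacks are stored
planar, one band per sample, in the order given by the caller's band-role
list.
"""

from __future__ import annotations

import os
import re

import numpy as np
import tifffile

from .errors import RasterIOError
from .geo import (
    DIGITAL_NUMBER,
    REFLECTANCE,
    BandStack,
    DEFAULT_BAND_ORDER,
    ElevationRaster,
    GridTransform,
)

# GeoTIFF / GDAL tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoKey ids
_GT_MODEL_TYPE = 1024
_GT_RASTER_TYPE = 1025
_PROJECTED_CS_TYPE = 3072


def _geo_extratags(transform: GridTransform, crs: str | None, nodata) -> list:
    tags = [
        (_MODEL_PIXEL_SCALE, 12, 3,
         (abs(transform.pixel_width), abs(transform.pixel_height), 0.0)),
        (_MODEL_TIEPOINT, 12, 6,
         (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0)),
    ]
    epsg = _epsg_code(crs)
    if epsg is not None:
        # minimal key directory: projected CRS, RasterPixelIsArea
        tags.append((_GEO_KEY_DIRECTORY, 3, 16,
                     (1, 1, 0, 3,
                      _GT_MODEL_TYPE, 0, 1, 1,
                      _GT_RASTER_TYPE, 0, 1, 1,
                      _PROJECTED_CS_TYPE, 0, 1, epsg)))
    if nodata is not None:
        txt = "nan" if isinstance(nodata, float) and np.isnan(nodata) else repr(float(nodata))
        tags.append((_GDAL_NODATA, 2, None, txt))
    return tags


def _epsg_code(crs: str | None) -> int | None:
    if crs is None:
        return None
    m = re.fullmatch(r"(?:EPSG:)?(\d+)", str(crs).strip(), flags=re.IGNORECASE)
    return int(m.group(1)) if m else None


def _read_geo(page) -> tuple[GridTransform, str | None, float | None]:
    tags = page.tags
    if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
        raise RasterIOError("file lacks GeoTIFF georeferencing tags")
    sx, sy, _ = tags[_MODEL_PIXEL_SCALE].value[:3]
    tp = tags[_MODEL_TIEPOINT].value
    # tie the raster (0, 0) corner to the world point; pixel row axis points south
    i, j, _, x, y, _ = tp[:6]
    origin_x = x - j * sx
    origin_y = y + i * sy
    transform = GridTransform(origin_x, origin_y, float(sx), -float(sy))
    crs = None
    if _GEO_KEY_DIRECTORY in tags:
        keys = tags[_GEO_KEY_DIRECTORY].value
        for k in range(4, len(keys), 4):
            if keys[k] == _PROJECTED_CS_TYPE:
                crs = f"EPSG:{keys[k + 3]}"
    nodata = None
    if _GDAL_NODATA in tags:
        nodata = float(tags[_GDAL_NODATA].value)
    return transform, crs, nodata


def _mask_nodata(grid: np.ndarray, nodata) -> np.ndarray:
    out = np.asarray(grid, dtype=np.float64)
    if nodata is not None and not np.isnan(nodata):
        out = np.where(out == nodata, np.nan, out)
    return out


def load_band_stack(path: str | os.PathLike,
                    band_order: list[str] | None = None) -> BandStack:
    """Load a multiband GeoTIFF, mapping bands to roles by ``band_order``.

    16-bit integer data is flagged as raw digital numbers, float data as
    reflectance. Raises on missing files, fewer bands than roles, or a
    band order with duplicate roles.
    """
    band_order = list(band_order or DEFAULT_BAND_ORDER)
    if len(set(band_order)) != len(band_order):
        raise RasterIOError(f"duplicate roles in band order {band_order}")
    if not os.path.exists(path):
        raise RasterIOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = tf.asarray()
        transform, crs, nodata = _read_geo(page)
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3 and data.shape[0] > 16 and data.shape[-1] <= 16:
        data = np.moveaxis(data, -1, 0)  # pixel-interleaved layout
    if data.shape[0] < len(band_order):
        raise RasterIOError(
            f"insufficient bands: file has {data.shape[0]}, need {len(band_order)}")
    domain = DIGITAL_NUMBER if np.issubdtype(data.dtype, np.integer) else REFLECTANCE
    bands = {role: _mask_nodata(data[i], nodata) for i, role in enumerate(band_order)}
    return BandStack(bands=bands, transform=transform, crs=crs,
                     nodata=nodata, value_domain=domain)


def write_band_stack(stack: BandStack, path: str | os.PathLike,
                     band_order: list[str] | None = None) -> None:
    """Write a BandStack as a planar multiband GeoTIFF."""
    band_order = list(band_order or DEFAULT_BAND_ORDER)
    if stack.value_domain == DIGITAL_NUMBER:
        data = np.stack([np.nan_to_num(stack.bands[r], nan=stack.nodata or 0)
                         for r in band_order]).astype(np.uint16)
        nodata = stack.nodata
    else:
        data = np.stack([stack.bands[r] for r in band_order]).astype(np.float32)
        nodata = float("nan")
    tifffile.imwrite(path, data, planarconfig="separate",
                     extratags=_geo_extratags(stack.transform, stack.crs, nodata))


def load_elevation(path: str | os.PathLike) -> ElevationRaster:
    """Load a single-band elevation GeoTIFF (meters)."""
    if not os.path.exists(path):
        raise RasterIOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = tf.asarray()
        transform, crs, nodata = _read_geo(page)
    if data.ndim != 2:
        data = np.squeeze(data)
        if data.ndim != 2:
            raise RasterIOError("elevation raster must be single-band")
    return ElevationRaster(elevation=_mask_nodata(data, nodata),
                           transform=transform, crs=crs, nodata=nodata)


def write_elevation(dem: ElevationRaster, path: str | os.PathLike) -> None:
    tifffile.imwrite(path, dem.elevation.astype(np.float32),
                     extratags=_geo_extratags(dem.transform, dem.crs, float("nan")))


def write_index_raster(grid: np.ndarray, name: str, template: BandStack,
                       path: str | os.PathLike) -> None:
    """Write a single-band float GeoTIFF on the template's grid; NaN = nodata."""
    if grid.shape != template.shape:
        raise RasterIOError(
            f"shape mismatch for {name!r}: {grid.shape} vs template {template.shape}")
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32),
                     description=name,
                     extratags=_geo_extratags(template.transform, template.crs,
                                              float("nan")))


def load_index_raster(path: str | os.PathLike) -> np.ndarray:
    """Reload a single-band float raster written by :func:`write_index_raster`."""
    with tifffile.TiffFile(path) as tf:
        return np.asarray(tf.asarray(), dtype=np.float64)
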