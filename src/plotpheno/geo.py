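"""Core georeferenced containers: band stacks, elevation rasters, plot polygons.

Conventions
-----------
* Pixel indices are 0-based ``(row, col)``.
* The world coordinate of a pixel is its **center**:
  ``x = origin_x + (col + 0.5) * pixel_width``,
  ``y = origin_y + (row + 0.5) * pixel_height`` (pixel_height is negative for
  north-up rasters, so row 0 is the northern edge).
* Rasterization includes a pixel iff its center lies strictly inside the
  polygon; centers exactly on the boundary are excluded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import EmptyPlotError, RasterIOError, VectorIOError

BAND_ROLES = ("blue", "green", "red", "rededge", "nir")
#: default MicaSense RedEdge band order in the multiband orthomosaic
DEFAULT_BAND_ORDER = list(BAND_ROLES)

DIGITAL_NUMBER = "digital_number"
REFLECTANCE = "reflectance"


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform (no rotation/shear terms).

    ``origin_x``/``origin_y`` are the world coordinates of the raster's
    top-left *corner*; ``pixel_width`` > 0, ``pixel_height`` < 0 for the
    usual north-up layout.
    """

    origin_x: float
    origin_y: float
    pixel_width: float
    pixel_height: float

    def __post_init__(self):
        if self.pixel_width == 0 or self.pixel_height == 0:
            raise RasterIOError("pixel size must be non-zero")

    @property
    def pixel_area(self) -> float:
        """Ground area of one pixel in m^2."""
        return abs(self.pixel_width * self.pixel_height)

    def pixel_to_world(self, row, col):
        """World coordinates of pixel centers (vectorized)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_width
        y = self.origin_y + (np.asarray(row) + 0.5) * self.pixel_height
        return x, y

    def world_to_pixel(self, x, y):
        """Fractional (row, col) of world points; center maps to integer index."""
        col = (np.asarray(x) - self.origin_x) / self.pixel_width - 0.5
        row = (np.asarray(y) - self.origin_y) / self.pixel_height - 0.5
        return row, col


@dataclass
class BandStack:
    """Five-band multispectral raster with named band roles.

    Bands are stored as float64 grids with NaN marking nodata; ``value_domain``
    records whether values are raw sensor digital numbers (0..65535) or
    surface reflectance (0..1).
    """

    bands: dict[str, np.ndarray]
    transform: GridTransform
    crs: str | None = None
    nodata: float | None = None
    value_domain: str = REFLECTANCE

    def __post_init__(self):
        missing = [r for r in BAND_ROLES if r not in self.bands]
        if missing:
            raise RasterIOError(f"insufficient bands: missing roles {missing}")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise RasterIOError(f"band shapes differ: {shapes}")
        if self.value_domain not in (DIGITAL_NUMBER, REFLECTANCE):
            raise RasterIOError(f"unknown value domain {self.value_domain!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    def validate_values(self) -> None:
        """Check the value-domain range invariant on finite pixels."""
        lo, hi = (0.0, 1.0) if self.value_domain == REFLECTANCE else (0.0, 65535.0)
        for role, grid in self.bands.items():
            finite = grid[np.isfinite(grid)]
            if finite.size and (finite.min() < lo or finite.max() > hi):
                raise RasterIOError(
                    f"band {role!r} outside [{lo}, {hi}] for {self.value_domain}"
                )


@dataclass
class ElevationRaster:
    """Single-band surface elevation grid in meters."""

    elevation: np.ndarray
    transform: GridTransform
    crs: str | None = None
    nodata: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    def check_aligned(self, stack: BandStack) -> None:
        """Refuse misaligned grids instead of silently resampling."""
        if self.shape != stack.shape or self.transform != stack.transform:
            raise RasterIOError(
                "DEM and orthomosaic grids are misaligned; resample upstream"
            )


@dataclass
class PlotPolygon:
    """One experimental plot: id, world-coordinate polygon, extra attributes."""

    plot_id: str
    geometry: Polygon
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise VectorIOError(f"plot {self.plot_id!r}: invalid or empty polygon")


def rasterize_polygon(
    poly: PlotPolygon,
    grid: BandStack | ElevationRaster,
    buffer: float = 0.0,
) -> np.ndarray:
    """Boolean membership grid: True where the pixel center is strictly inside.

    ``buffer`` < 0 shrinks the polygon inward (edge-pixel avoidance); the
    default 0 uses the polygon as digitized.
    """
    geom = poly.geometry if buffer == 0.0 else poly.geometry.buffer(buffer)
    if geom.is_empty:
        raise EmptyPlotError(poly.plot_id)
    t = grid.transform
    nrow, ncol = grid.shape

    # restrict the point-in-polygon test to the bounding-box pixel window
    minx, miny, maxx, maxy = geom.bounds
    rows_f, cols_f = t.world_to_pixel(np.array([minx, maxx]), np.array([miny, maxy]))
    r0 = max(int(np.floor(rows_f.min())) - 1, 0)
    r1 = min(int(np.ceil(rows_f.max())) + 2, nrow)
    c0 = max(int(np.floor(cols_f.min())) - 1, 0)
    c1 = min(int(np.ceil(cols_f.max())) + 2, ncol)

    membership = np.zeros((nrow, ncol), dtype=bool)
    if r0 < r1 and c0 < c1:
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        x, y = t.pixel_to_world(rr.ravel(), cc.ravel())
        # shapely contains() excludes the boundary, matching the convention
        inside = shapely.contains_xy(geom, x, y).reshape(rr.shape)
        membership[r0:r1, c0:c1] = inside
    if not membership.any():
        raise EmptyPlotError(poly.plot_id)
    return membership
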