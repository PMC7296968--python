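"""Canopy structure from the elevation model: height, cover, volume.

Heights are measured above a per-plot ground reference estimated from soil
pixels (the canopy mask identifies them). Plot-level canonical metrics:

* CHuav — 95th percentile of per-pixel canopy height (linear interpolation
  between order statistics at index p*(n-1));
* CCuav — total ground area covered by canopy pixels, m^2;
* CVuav — sum over canopy pixels of covered area x height, m^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyPlotError, RasterIOError
from .geo import ElevationRaster, PlotPolygon, rasterize_polygon
from .segmentation import CanopyMask


@dataclass
class CanopyLayers:
    """Per-pixel canopy layers restricted to one plot's pixels."""

    height: np.ndarray        # m above ground; NaN off-canopy / off-plot
    cover: np.ndarray         # m^2: pixel_area on canopy pixels, 0 elsewhere
    volume: np.ndarray        # m^3 = cover * height (0 off-canopy)
    pixel_area: float
    ground_elevation: float


@dataclass
class PlotCanopySummary:
    plot_id: str
    CHuav: float   # m
    CCuav: float   # m^2
    CVuav: float   # m^3


def estimate_ground_elevation(dem: ElevationRaster, plot: PlotPolygon,
                              mask: CanopyMask,
                              membership: np.ndarray | None = None,
                              min_soil_fraction: float = 0.05,
                              fallback_percentile: float = 5.0) -> float:
    """Median DEM over the plot's soil pixels.

    Falls back to a low percentile of all plot elevations when fewer than
    ``min_soil_fraction`` of the plot's pixels are soil (fully closed canopy).
    """
    if membership is None:
        membership = rasterize_polygon(plot, dem)
    elev = dem.elevation
    plot_vals = elev[membership & np.isfinite(elev)]
    if plot_vals.size == 0:
        raise EmptyPlotError(plot.plot_id)
    soil = membership & (mask.mask == 0) & np.isfinite(elev)
    if soil.sum() >= min_soil_fraction * membership.sum() and soil.sum() > 0:
        return float(np.median(elev[soil]))
    return float(np.percentile(plot_vals, fallback_percentile))


def compute_canopy_layers(dem: ElevationRaster, mask: CanopyMask,
                          plot: PlotPolygon,
                          membership: np.ndarray | None = None,
                          ground_elevation: float | None = None) -> CanopyLayers:
    """Height/cover/volume grids for one plot (NaN/0 outside it)."""
    if dem.shape != mask.aligned_to:
        raise RasterIOError("DEM and canopy mask grids are misaligned")
    if membership is None:
        membership = rasterize_polygon(plot, dem)
    if ground_elevation is None:
        ground_elevation = estimate_ground_elevation(dem, plot, mask, membership)

    pixel_area = dem.transform.pixel_area
    canopy = membership & (mask.mask == 1)
    height = np.full(dem.shape, np.nan)
    # negative heights (soil below the reference) are not physical: floor at 0
    height[canopy] = np.maximum(dem.elevation[canopy] - ground_elevation, 0.0)
    cover = np.where(canopy, pixel_area, 0.0)
    volume = np.where(canopy, cover * np.nan_to_num(height), 0.0)
    return CanopyLayers(height=height, cover=cover, volume=volume,
                        pixel_area=pixel_area, ground_elevation=ground_elevation)


def plot_canopy_summary(layers: CanopyLayers, membership: np.ndarray,
                        plot_id: str = "",
                        height_percentile: float = 95.0) -> PlotCanopySummary:
    """Canonical CHuav/CCuav/CVuav over one plot's pixels."""
    if not membership.any():
        raise EmptyPlotError(plot_id or "<membership>")
    heights = layers.height[membership]
    heights = heights[np.isfinite(heights)]
    ch = float(np.percentile(heights, height_percentile)) if heights.size else 0.0
    cc = float(layers.cover[membership].sum())
    cv = float(layers.volume[membership].sum())
    return PlotCanopySummary(plot_id=plot_id, CHuav=ch, CCuav=cc, CVuav=cv)
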