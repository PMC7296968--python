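"""Plot-level feature extraction: zonal statistics over index and canopy layers.

Each plot yields 7 statistics (mean, variance, median, std, sum, min, max)
for each of 11 layers (the eight vegetation indices plus canopy height,
cover, volume) — 77 feature columns per timing point. Index and height
statistics run over canopy pixels only; cover and volume run over all plot
pixels because off-canopy zeros are genuine area/volume contributions.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import NoValidPixelsError, PlotPhenoError
from .geo import BandStack, ElevationRaster, PlotPolygon, rasterize_polygon
from .indices import INDEX_NAMES, compute_index
from .metrics import compute_canopy_layers
from .segmentation import CanopyMask

log = logging.getLogger(__name__)

STATISTICS = ("mean", "variance", "median", "std", "sum", "min", "max")
CANOPY_LAYERS = ("canopy_height", "canopy_cover", "canopy_volume")
FEATURE_LAYERS = tuple(n.lower() for n in INDEX_NAMES) + CANOPY_LAYERS
#: the per-timing-point feature contract: 11 layers x 7 statistics
FEATURE_COLUMNS = tuple(sorted(f"{layer}_{stat}"
                               for layer in FEATURE_LAYERS for stat in STATISTICS))
KEY_COLUMNS = ("plot_id", "timing_point", "timestamp")


def summarize_layer(values) -> dict[str, float]:
    """The seven zonal statistics of a finite pixel population.

    Sample variance uses the n-1 denominator (0 for a single pixel); the
    median of an even count is the mean of the central pair.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise NoValidPixelsError("<layer>", "<plot>")
    var = float(np.var(v, ddof=1)) if v.size > 1 else 0.0
    return {
        "mean": float(np.mean(v)),
        "variance": var,
        "median": float(np.median(v)),
        "std": float(np.sqrt(var)),
        "sum": float(np.sum(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
    }


def build_feature_table(stack: BandStack, dem: ElevationRaster,
                        plots: list[PlotPolygon], mask: CanopyMask,
                        timing_point: str, timestamp: str = "",
                        buffer: float = 0.0) -> pd.DataFrame:
    """One row per plot with the 77 feature columns for one timing point.

    Plots without a single canopy pixel get NaN for index/height statistics
    (zeros would fabricate spectral signal) and are logged, never dropped.
    """
    dem.check_aligned(stack)
    index_rasters = {name.lower(): compute_index(stack, name, mask=mask).values
                     for name in INDEX_NAMES}

    rows = []
    for plot in plots:
        membership = rasterize_polygon(plot, stack, buffer=buffer)
        layers = compute_canopy_layers(dem, mask, plot, membership=membership)
        row: dict[str, float | str] = {"plot_id": plot.plot_id,
                                       "timing_point": timing_point,
                                       "timestamp": timestamp}
        canopy_pixels = int(np.isfinite(layers.height[membership]).sum())
        if canopy_pixels == 0:
            log.warning("plot %s has no canopy pixels at %s; index/height "
                        "statistics reported missing", plot.plot_id, timing_point)

        for layer_name, grid, canopy_only in (
            [(n, g, True) for n, g in index_rasters.items()]
            + [("canopy_height", layers.height, True),
               ("canopy_cover", layers.cover, False),
               ("canopy_volume", layers.volume, False)]
        ):
            vals = grid[membership]
            if canopy_only:
                vals = vals[np.isfinite(vals)]
            try:
                stats = summarize_layer(vals)
            except NoValidPixelsError:
                stats = {s: np.nan for s in STATISTICS}
            for stat, value in stats.items():
                row[f"{layer_name}_{stat}"] = value
        rows.append(row)

    table = pd.DataFrame(rows, columns=list(KEY_COLUMNS) + list(FEATURE_COLUMNS))
    assert len(table.columns) == len(KEY_COLUMNS) + 77, "77-feature contract broken"
    return table


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """CSV report: key columns first, then features in sorted order."""
    if table.empty:
        raise PlotPhenoError("refusing to write an empty feature table")
    feature_cols = sorted(c for c in table.columns if c not in KEY_COLUMNS)
    ordered = [c for c in KEY_COLUMNS if c in table.columns] + feature_cols
    table[ordered].to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"plot_id": str, "timing_point": str})


@dataclass
class AssociationResult:
    """Pearson correlation between a plot feature and a ground-truth trait."""

    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def trait_correlation(x, y) -> AssociationResult:
    """Pearson r with the two-sided p-value from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("feature and trait vectors differ in length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(x, y)
    return AssociationResult(r=float(r), p=float(p), n=int(x.size))
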