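"""Canopy height/cover/volume layers and the plot-level canonical metrics."""

import numpy as np
import pytest
from shapely.geometry import box

from plotpheno import (
    GridTransform,
    PlotPolygon,
    compute_canopy_layers,
    estimate_ground_elevation,
    plot_canopy_summary,
    rasterize_polygon,
)
from plotpheno.geo import ElevationRaster
from plotpheno.segmentation import CanopyMask


def build(nrow=12, ncol=12, px=0.1, ground=100.0):
    t = GridTransform(0.0, 0.0, px, -px)
    dem = ElevationRaster(elevation=np.full((nrow, ncol), ground), transform=t)
    mask = CanopyMask(mask=np.zeros((nrow, ncol), dtype=np.uint8),
                      threshold=0.0, aligned_to=(nrow, ncol))
    poly = PlotPolygon("P1", box(0.0, -nrow * px, ncol * px, 0.0))
    return dem, mask, poly


def test_ground_elevation_flat_ground_with_mounds():
    dem, mask, poly = build()
    mask.mask[2:6, 2:6] = 1
    dem.elevation[2:6, 2:6] = 102.0  # mounds on the canopy pixels
    assert estimate_ground_elevation(dem, poly, mask) == pytest.approx(100.0)


def test_ground_elevation_fallback_percentile_under_full_canopy(rng):
    dem, mask, poly = build()
    mask.mask[:, :] = 1
    dem.elevation[:, :] = 100.0 + rng.uniform(0, 2.5, dem.shape)
    g = estimate_ground_elevation(dem, poly, mask)
    member = rasterize_polygon(poly, dem)
    oracle = np.percentile(dem.elevation[member], 5.0)
    assert g == pytest.approx(oracle)
    assert 100.0 <= g <= 102.5


def test_ground_elevation_equals_median_oracle(rng):
    dem, mask, poly = build()
    soil_vals = rng.normal(100, 0.5, dem.shape)
    dem.elevation[:, :] = soil_vals
    mask.mask[0:3, :] = 1  # some canopy; rest soil
    member = rasterize_polygon(poly, dem)
    soil = member & (mask.mask == 0)
    assert estimate_ground_elevation(dem, poly, mask) == pytest.approx(
        np.median(sorted(dem.elevation[soil])))


def test_layers_direct_products():
    # 10 canopy pixels of 0.01 m^2, each 2 m tall -> cover 0.1 m^2, volume 0.2 m^3
    dem, mask, poly = build()
    mask.mask[5, 0:10] = 1
    dem.elevation[5, 0:10] = 102.0
    layers = compute_canopy_layers(dem, mask, poly, ground_elevation=100.0)
    assert layers.pixel_area == pytest.approx(0.01)
    assert np.nansum(layers.cover) == pytest.approx(0.1)
    assert np.nansum(layers.volume) == pytest.approx(0.2)


def test_layers_zero_canopy_degenerate():
    dem, mask, poly = build()
    layers = compute_canopy_layers(dem, mask, poly, ground_elevation=100.0)
    assert np.all(layers.cover == 0)
    assert np.all(np.isnan(layers.height))
    summary = plot_canopy_summary(layers, rasterize_polygon(poly, dem), "P1")
    assert summary.CHuav == 0.0 and summary.CCuav == 0.0 and summary.CVuav == 0.0


def test_layers_match_elementwise_oracle(rng):
    dem, mask, poly = build()
    dem.elevation[:, :] = 100.0 + rng.uniform(-0.5, 3.0, dem.shape)
    mask.mask[:, :] = rng.integers(0, 2, dem.shape)
    member = rasterize_polygon(poly, dem)
    layers = compute_canopy_layers(dem, mask, poly, membership=member,
                                   ground_elevation=100.0)
    for i in range(dem.shape[0]):
        for j in range(dem.shape[1]):
            if member[i, j] and mask.mask[i, j] == 1:
                h = max(dem.elevation[i, j] - 100.0, 0.0)
                assert layers.height[i, j] == pytest.approx(h)
                assert layers.cover[i, j] == pytest.approx(0.01)
                assert layers.volume[i, j] == pytest.approx(0.01 * h)
            else:
                assert np.isnan(layers.height[i, j])
                assert layers.cover[i, j] == 0.0


def test_chuav_constant_and_interpolated_percentile():
    dem, mask, poly = build(nrow=10, ncol=10)
    mask.mask[:, :] = 1
    member = rasterize_polygon(poly, dem)
    # constant height h -> CHuav = h
    dem.elevation[:, :] = 101.7
    layers = compute_canopy_layers(dem, mask, poly, membership=member,
                                   ground_elevation=100.0)
    assert plot_canopy_summary(layers, member).CHuav == pytest.approx(1.7)
    # heights 0..99 -> 95th percentile with p*(n-1) indexing = 94.05
    dem.elevation[:, :] = 100.0 + np.arange(100.0).reshape(10, 10)
    layers = compute_canopy_layers(dem, mask, poly, membership=member,
                                   ground_elevation=100.0)
    assert plot_canopy_summary(layers, member).CHuav == pytest.approx(94.05)


def test_cvuav_equals_independent_summation_oracle(rng):
    dem, mask, poly = build()
    dem.elevation[:, :] = 100.0 + rng.uniform(0, 3, dem.shape)
    mask.mask[:, :] = rng.integers(0, 2, dem.shape)
    member = rasterize_polygon(poly, dem)
    layers = compute_canopy_layers(dem, mask, poly, membership=member,
                                   ground_elevation=100.0)
    summary = plot_canopy_summary(layers, member, "P1")

    cv = 0.0
    for i in range(dem.shape[0]):
        for j in range(dem.shape[1]):
            if member[i, j] and mask.mask[i, j] == 1:
                cv += 0.01 * max(dem.elevation[i, j] - 100.0, 0.0)
    assert summary.CVuav == pytest.approx(cv, abs=1e-12)
    # CCuav = canopy pixel count x pixel area, exactly
    n_canopy = int((member & (mask.mask == 1)).sum())
    assert summary.CCuav == pytest.approx(n_canopy * 0.01, abs=1e-12)


def test_cvuav_additive_under_plot_splitting(rng):
    """Splitting a plot into halves and summing CVuav reproduces the whole."""
    dem, mask, _ = build(nrow=10, ncol=10)
    dem.elevation[:, :] = 100.0 + rng.uniform(0, 3, dem.shape)
    mask.mask[:, :] = rng.integers(0, 2, dem.shape)
    whole = PlotPolygon("W", box(0.0, -1.0, 1.0, 0.0))
    left = PlotPolygon("L", box(0.0, -1.0, 0.5, 0.0))
    right = PlotPolygon("R", box(0.5, -1.0, 1.0, 0.0))

    def cv(poly):
        m = rasterize_polygon(poly, dem)
        layers = compute_canopy_layers(dem, mask, poly, membership=m,
                                       ground_elevation=100.0)
        return plot_canopy_summary(layers, m, poly.plot_id).CVuav

    assert cv(whole) == pytest.approx(cv(left) + cv(right), abs=1e-12)


def test_chuav_monotone_in_pixel_height(rng):
    dem, mask, poly = build()
    dem.elevation[:, :] = 100.0 + rng.uniform(0, 2, dem.shape)
    mask.mask[:, :] = 1
    member = rasterize_polygon(poly, dem)

    def chuav():
        layers = compute_canopy_layers(dem, mask, poly, membership=member,
                                       ground_elevation=100.0)
        return plot_canopy_summary(layers, member).CHuav

    before = chuav()
    dem.elevation[4, 4] += 5.0
    assert chuav() >= before
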