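"""Synthetic field trials: scenes, plots, panels and ground truth.

The generator renders a gridded cassava-style trial the way the imaging
pipeline expects to see one: a five-band reflectance (or raw digital
number) orthomosaic over soil with circular canopy blobs per plot, a DEM of
a gently sloping ground plane plus plant heights, calibration panels of
known reflectance in a strip above the plots, and a trait table whose root
yield is a stated noisy linear function of the plots' true (noise-free)
NDVI and canopy volume:

    yield = beta0 + beta1 * NDVI_true + beta2 * CV_true + eps,
    eps ~ N(0, eps_sd^2)

Per-plot variation comes from a vigor factor (scales plant height, hence
canopy volume) and an independent NDVI jitter, so the theoretical R^2 of
the yield model has the closed form

    R^2 = S / (S + eps_sd^2),
    S = beta1^2 sd_ndvi^2 + beta2^2 (CV_base * vigor_sd)^2.

Every truth artifact (mask, calibration line, coefficients, theoretical
R^2) is exposed so downstream modules can be tested against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .calibration import CalibrationPanel, LinearCalibration
from .errors import PlotPhenoError
from .geo import (
    BAND_ROLES,
    DIGITAL_NUMBER,
    REFLECTANCE,
    BandStack,
    ElevationRaster,
    GridTransform,
    PlotPolygon,
)

#: stage -> (canopy fraction, height multiplier); canopy closes and plants
#: grow from elongation to late bulking, then hold through dry-matter
#: accumulation
STAGE_PARAMS = {
    "EL": (0.35, 0.5),
    "EBK": (0.55, 0.8),
    "LBK": (0.75, 1.0),
    "DMA": (0.75, 1.0),
}


@dataclass
class SyntheticFieldSpec:
    """Full parameterization of a synthetic trial (fixed seed => fixed data)."""

    seed: int = 0
    pixel_size: float = 0.2                  # m
    plot_rows: int = 9
    plot_cols: int = 15
    plot_width: float = 4.0                  # m
    plot_height: float = 4.0                 # m
    spacing: float = 1.0                     # m between plots
    margin: float = 4.0                      # m field border
    panel_strip: float = 3.0                 # m strip above plots for panels
    origin_x: float = 500000.0
    origin_y: float = 4200000.0
    crs: str = "EPSG:32618"
    grid_width_m: float | None = None        # optional hard extent limits
    grid_height_m: float | None = None

    soil_spectrum: dict = field(default_factory=lambda: {
        "blue": 0.12, "green": 0.18, "red": 0.20, "rededge": 0.24, "nir": 0.28})
    plant_spectrum: dict = field(default_factory=lambda: {
        "blue": 0.05, "green": 0.25, "red": 0.10, "rededge": 0.35, "nir": 0.55})

    plant_height_mean: float = 1.8           # m, at height multiplier 1
    pixel_height_sd: float = 0.05            # m, within-canopy texture
    vigor_sd: float = 0.12                   # per-plot height/volume variation
    ndvi_jitter_sd: float = 0.03             # per-plot spectral variation

    noise_sd_reflectance: float = 0.01
    noise_sd_dn: float = 50.0

    gain: dict = field(default_factory=lambda: {
        "blue": 1.2e-5, "green": 1.1e-5, "red": 1.0e-5,
        "rededge": 0.9e-5, "nir": 0.8e-5})
    offset: dict = field(default_factory=lambda: {r: 0.01 for r in BAND_ROLES})
    panel_reflectances: tuple = (0.05, 0.20, 0.35, 0.50)
    panel_size: float = 1.5                  # m

    ground_elevation: float = 100.0          # m
    ground_slope: float = 0.005              # m per m easting

    n_replications: int = 4
    n_genotypes: int = 5
    yield_stage: str = "LBK"
    beta0: float = 5.0
    beta1: float = 40.0                      # per unit NDVI
    beta2: float = 1.0                       # per m^3 canopy volume
    eps_sd: float = 2.0                      # yield units

    # ------------------------------------------------------------------ layout
    @property
    def field_width(self) -> float:
        return (2 * self.margin + self.plot_cols * self.plot_width
                + (self.plot_cols - 1) * self.spacing)

    @property
    def field_height(self) -> float:
        return (2 * self.margin + self.panel_strip
                + self.plot_rows * self.plot_height
                + (self.plot_rows - 1) * self.spacing)

    @property
    def n_plots(self) -> int:
        return self.plot_rows * self.plot_cols

    @property
    def plot_area(self) -> float:
        return self.plot_width * self.plot_height

    def validate(self) -> None:
        if self.grid_width_m is not None and self.field_width > self.grid_width_m:
            raise PlotPhenoError("plot layout exceeds the requested grid width")
        if self.grid_height_m is not None and self.field_height > self.grid_height_m:
            raise PlotPhenoError("plot layout exceeds the requested grid height")
        for spec in (self.soil_spectrum, self.plant_spectrum):
            for role, v in spec.items():
                if not 0 <= v <= 1:
                    raise PlotPhenoError(f"spectrum value {v} for {role} outside [0,1]")
        if not 0 < len(self.panel_reflectances):
            raise PlotPhenoError("at least one panel reflectance required")

    def transform(self) -> GridTransform:
        return GridTransform(self.origin_x, self.origin_y,
                             self.pixel_size, -self.pixel_size)

    def raster_shape(self) -> tuple[int, int]:
        return (int(round(self.field_height / self.pixel_size)),
                int(round(self.field_width / self.pixel_size)))

    # ------------------------------------------------------------ yield model
    def base_ndvi(self) -> float:
        a, b = self.plant_spectrum["nir"], self.plant_spectrum["red"]
        return (a - b) / (a + b)

    def base_canopy_volume(self, stage: str | None = None) -> float:
        frac, hmult = STAGE_PARAMS[stage or self.yield_stage]
        return self.plot_area * frac * self.plant_height_mean * hmult

    def theoretical_r2(self, stage: str | None = None) -> float:
        """Var(signal) / Var(total) of the yield model, in closed form."""
        s = (self.beta1 ** 2 * self.ndvi_jitter_sd ** 2
             + self.beta2 ** 2 * (self.base_canopy_volume(stage) * self.vigor_sd) ** 2)
        return s / (s + self.eps_sd ** 2)


@dataclass
class SyntheticScene:
    """One rendered stage plus every truth artifact needed by oracle tests."""

    stage: str
    stack: BandStack
    dem: ElevationRaster
    truth_mask: np.ndarray            # uint8, 1 = canopy
    plots: list[PlotPolygon]
    panels: list[CalibrationPanel]
    calibration: LinearCalibration    # the generating (truth) line
    plot_truth: pd.DataFrame


# --------------------------------------------------------------------------
# per-plot latent truth (shared across stages)
# --------------------------------------------------------------------------

def plot_truth(spec: SyntheticFieldSpec) -> pd.DataFrame:
    """Per-plot latent variables: replication, genotype, vigor, NDVI jitter."""
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_plots
    per_rep = int(np.ceil(n / spec.n_replications))
    rows = []
    for idx in range(n):
        r, c = divmod(idx, spec.plot_cols)
        rows.append({
            "plot_id": f"P{idx + 1:03d}",
            "row": r,
            "col": c,
            "replication": f"R{idx // per_rep + 1}",
            "genotype": f"G{idx % spec.n_genotypes + 1}",
        })
    df = pd.DataFrame(rows)
    df["vigor"] = rng.normal(1.0, spec.vigor_sd, size=n)
    df["ndvi_jitter"] = rng.normal(0.0, spec.ndvi_jitter_sd, size=n)
    df["true_ndvi"] = np.clip(spec.base_ndvi() + df["ndvi_jitter"], -0.99, 0.99)
    return df


def plot_polygons(spec: SyntheticFieldSpec,
                  truth: pd.DataFrame | None = None) -> list[PlotPolygon]:
    """Rectangular plot polygons in the gridded layout."""
    truth = truth if truth is not None else plot_truth(spec)
    plots = []
    for rec in truth.itertuples():
        x0 = (spec.origin_x + spec.margin
              + rec.col * (spec.plot_width + spec.spacing))
        y1 = (spec.origin_y - spec.margin - spec.panel_strip
              - rec.row * (spec.plot_height + spec.spacing))
        geom = box(x0, y1 - spec.plot_height, x0 + spec.plot_width, y1)
        plots.append(PlotPolygon(plot_id=rec.plot_id, geometry=geom,
                                 attributes={"replication": rec.replication,
                                             "genotype": rec.genotype}))
    return plots


def panel_polygons(spec: SyntheticFieldSpec) -> list[CalibrationPanel]:
    """Gray panels of known reflectance in the strip above the plots."""
    if len(spec.panel_reflectances) < 1:
        raise PlotPhenoError("no panel reflectances configured")
    panels = []
    y1 = spec.origin_y - 0.5
    for i, refl in enumerate(spec.panel_reflectances):
        x0 = spec.origin_x + spec.margin + i * (spec.panel_size + 1.0)
        if x0 + spec.panel_size > spec.origin_x + spec.field_width:
            raise PlotPhenoError("panels do not fit in the panel strip")
        geom = box(x0, y1 - spec.panel_size, x0 + spec.panel_size, y1)
        panels.append(CalibrationPanel(
            panel_id=f"PAN{i + 1}", geometry=geom,
            known_reflectance={r: float(refl) for r in BAND_ROLES}))
    return panels


def truth_calibration(spec: SyntheticFieldSpec) -> LinearCalibration:
    return LinearCalibration(gain=dict(spec.gain), offset=dict(spec.offset),
                             n_targets=len(spec.panel_reflectances))


# --------------------------------------------------------------------------
# scene rendering
# --------------------------------------------------------------------------

def generate_scene(spec: SyntheticFieldSpec, stage: str = "LBK",
                   mode: str = REFLECTANCE) -> SyntheticScene:
    """Render one stage: band stack, DEM, truth mask, plots and panels."""
    spec.validate()
    if stage not in STAGE_PARAMS:
        raise PlotPhenoError(f"unknown stage {stage!r}")
    if mode not in (REFLECTANCE, DIGITAL_NUMBER):
        raise PlotPhenoError(f"unknown scene mode {mode!r}")
    frac, hmult = STAGE_PARAMS[stage]
    truth = plot_truth(spec)
    plots = plot_polygons(spec, truth)
    panels = panel_polygons(spec)
    transform = spec.transform()
    ny, nx = spec.raster_shape()
    stage_idx = list(STAGE_PARAMS).index(stage)
    rng = np.random.default_rng([spec.seed, 10 + stage_idx])

    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    X, Y = transform.pixel_to_world(rows, cols)

    bands = {r: np.full((ny, nx), spec.soil_spectrum[r]) for r in BAND_ROLES}
    ground = (spec.ground_elevation
              + spec.ground_slope * (X - spec.origin_x))
    dem_values = ground.copy()
    mask = np.zeros((ny, nx), dtype=np.uint8)

    heights, fracs, ndvis = [], [], []
    for plot, rec in zip(plots, truth.itertuples()):
        cx, cy = plot.geometry.centroid.x, plot.geometry.centroid.y
        radius = np.sqrt(frac * spec.plot_area / np.pi)
        inside = (X - cx) ** 2 + (Y - cy) ** 2 < radius ** 2
        mask[inside] = 1

        # per-plot spectrum: NIR adjusted so plot NDVI equals its true value
        ndvi = float(rec.true_ndvi)
        spectrum = dict(spec.plant_spectrum)
        red = spectrum["red"]
        spectrum["nir"] = red * (1 + ndvi) / (1 - ndvi)
        for role in BAND_ROLES:
            bands[role][inside] = spectrum[role]

        h = spec.plant_height_mean * hmult * float(rec.vigor)
        pix_h = h + rng.normal(0.0, spec.pixel_height_sd, size=int(inside.sum()))
        dem_values[inside] = ground[inside] + np.maximum(pix_h, 0.0)
        heights.append(h)
        fracs.append(frac)
        ndvis.append(ndvi)

    for panel in panels:
        minx, miny, maxx, maxy = panel.geometry.bounds
        inside = (X >= minx) & (X < maxx) & (Y > miny) & (Y <= maxy)
        for role in BAND_ROLES:
            bands[role][inside] = panel.known_reflectance[role]

    if mode == REFLECTANCE:
        if spec.noise_sd_reflectance > 0:
            for role in BAND_ROLES:
                bands[role] = bands[role] + rng.normal(
                    0.0, spec.noise_sd_reflectance, size=(ny, nx))
        out_bands = {r: np.clip(b, 0.0, 1.0).astype(np.float32).astype(np.float64)
                     for r, b in bands.items()}
        stack = BandStack(bands=out_bands, transform=transform, crs=spec.crs,
                          value_domain=REFLECTANCE)
    else:
        out_bands = {}
        for role in BAND_ROLES:
            dn = (bands[role] - spec.offset[role]) / spec.gain[role]
            if spec.noise_sd_dn > 0:
                dn = dn + rng.normal(0.0, spec.noise_sd_dn, size=(ny, nx))
            out_bands[role] = np.clip(np.rint(dn), 0, 65535)
        stack = BandStack(bands=out_bands, transform=transform, crs=spec.crs,
                          value_domain=DIGITAL_NUMBER)

    stage_truth = truth.copy()
    stage_truth["stage"] = stage
    stage_truth["canopy_fraction"] = fracs
    stage_truth["plant_height"] = heights
    stage_truth["true_canopy_volume"] = (
        spec.plot_area * np.asarray(fracs) * np.asarray(heights))

    dem = ElevationRaster(elevation=dem_values, transform=transform, crs=spec.crs)
    return SyntheticScene(stage=stage, stack=stack, dem=dem, truth_mask=mask,
                          plots=plots, panels=panels,
                          calibration=truth_calibration(spec),
                          plot_truth=stage_truth)


def generate_panels(spec: SyntheticFieldSpec, stage: str = "LBK"
                    ) -> tuple[list[CalibrationPanel], LinearCalibration]:
    """Panel polygons plus the generating calibration line (truth)."""
    return panel_polygons(spec), truth_calibration(spec)


# --------------------------------------------------------------------------
# ground truth traits
# --------------------------------------------------------------------------

def generate_ground_truth(spec: SyntheticFieldSpec,
                          stage: str | None = None) -> pd.DataFrame:
    """Trait table: yield drawn from the stated model on true features.

    AGB / CH / LAI are derived from the same latent truth with small
    independent measurement noise; BGB is the storage-root compartment and
    equals root yield.
    """
    stage = stage or spec.yield_stage
    frac, hmult = STAGE_PARAMS[stage]
    truth = plot_truth(spec)
    rng = np.random.default_rng([spec.seed, 5])

    height = spec.plant_height_mean * hmult * truth["vigor"].to_numpy()
    cv = spec.plot_area * frac * height
    ndvi = truth["true_ndvi"].to_numpy()
    eps = rng.normal(0.0, spec.eps_sd, size=len(truth)) if spec.eps_sd > 0 \
        else np.zeros(len(truth))
    y = spec.beta0 + spec.beta1 * ndvi + spec.beta2 * cv + eps

    out = truth[["plot_id", "replication", "genotype"]].copy()
    out["stage"] = stage
    out["true_ndvi"] = ndvi
    out["true_canopy_volume"] = cv
    out["AGB"] = 0.5 * cv + rng.normal(0.0, 0.2, size=len(truth))
    out["BGB"] = y
    out["CH"] = height + rng.normal(0.0, 0.02, size=len(truth))
    out["LAI"] = 6.0 * frac + rng.normal(0.0, 0.1, size=len(truth))
    out["root_yield"] = y
    return out


# --------------------------------------------------------------------------
# writing a trial to disk in the pipeline's input formats
# --------------------------------------------------------------------------

def write_trial(spec: SyntheticFieldSpec, outdir: str | Path,
                stages: list[str] | None = None,
                mode: str = DIGITAL_NUMBER) -> dict:
    """Write orthomosaics, DEMs, shapefiles, panel config, traits and truth."""
    from . import geotiff, shapefile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or list(STAGE_PARAMS)
    paths: dict = {"stages": {}}
    for stage in stages:
        scene = generate_scene(spec, stage, mode=mode)
        ortho = outdir / f"ortho_{stage}.tif"
        dem = outdir / f"dem_{stage}.tif"
        tmask = outdir / f"truth_mask_{stage}.tif"
        geotiff.write_band_stack(scene.stack, ortho)
        geotiff.write_elevation(scene.dem, dem)
        geotiff.write_index_raster(scene.truth_mask.astype(np.float64),
                                   "truth_mask", scene.stack, tmask)
        paths["stages"][stage] = {"ortho": str(ortho), "dem": str(dem),
                                  "truth_mask": str(tmask)}

    scene = generate_scene(spec, stages[0], mode=mode)
    shapefile.write_polygons(scene.plots, outdir / "plots.shp", crs=spec.crs)
    shapefile.write_polygons(
        [p for p in _panels_as_plots(scene.panels)],
        outdir / "panels.shp", id_field="panel_id", crs=spec.crs)
    panel_cfg = {p.panel_id: p.known_reflectance for p in scene.panels}
    (outdir / "panel_reflectance.json").write_text(
        json.dumps(panel_cfg, indent=2, sort_keys=True))

    traits = generate_ground_truth(spec)
    traits.to_csv(outdir / "traits.csv", index=False, lineterminator="\n")

    truth = {
        "spec": {k: v for k, v in dataclasses.asdict(spec).items()
                 if not isinstance(v, np.ndarray)},
        "theoretical_r2": spec.theoretical_r2(),
        "calibration_gain": spec.gain,
        "calibration_offset": spec.offset,
        "yield_betas": [spec.beta0, spec.beta1, spec.beta2],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))

    paths.update({"plots": str(outdir / "plots.shp"),
                  "panels": str(outdir / "panels.shp"),
                  "panel_reflectance": str(outdir / "panel_reflectance.json"),
                  "traits": str(outdir / "traits.csv"),
                  "truth": str(outdir / "truth.json")})
    return paths


def _panels_as_plots(panels: list[CalibrationPanel]) -> list[PlotPolygon]:
    return [PlotPolygon(plot_id=p.panel_id, geometry=p.geometry) for p in panels]
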