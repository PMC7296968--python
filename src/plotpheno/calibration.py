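"""Empirical Line Calibration: digital numbers -> surface reflectance.

A per-band linear model ``reflectance = gain * DN + offset`` is fitted by
ordinary least squares to ground targets (calibration panels) of known
reflectance, then applied to the whole orthomosaic, clipping the result to
the physical [0, 1] range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import InsufficientTargetsError, SingularFitError
from .geo import (
    DIGITAL_NUMBER,
    REFLECTANCE,
    BandStack,
    PlotPolygon,
    rasterize_polygon,
)

log = logging.getLogger(__name__)


@dataclass
class CalibrationPanel:
    """Ground target of known reflectance, one value per band role."""

    panel_id: str
    geometry: Polygon
    known_reflectance: dict[str, float]

    def __post_init__(self):
        for role, r in self.known_reflectance.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"panel {self.panel_id}: reflectance {r} for "
                                 f"{role} outside [0, 1]")


@dataclass
class LinearCalibration:
    """Fitted per-band gain/offset with RMS fit residuals."""

    gain: dict[str, float]
    offset: dict[str, float]
    n_targets: int
    residual: dict[str, float] = field(default_factory=dict)


def panel_digital_numbers(stack: BandStack, panel: CalibrationPanel,
                          statistic: str = "mean") -> dict[str, float]:
    """Per-band summary DN over the panel's pixels (mean, or median)."""
    member = rasterize_polygon(
        PlotPolygon(plot_id=panel.panel_id, geometry=panel.geometry), stack)
    reducer = np.nanmedian if statistic == "median" else np.nanmean
    return {role: float(reducer(grid[member]))
            for role, grid in stack.bands.items()}


def fit_elc(stack: BandStack, panels: list[CalibrationPanel],
            statistic: str = "mean") -> LinearCalibration:
    """OLS line fit of known reflectance against mean panel DN, per band."""
    if stack.value_domain != DIGITAL_NUMBER:
        raise ValueError("fit_elc expects a digital-number stack")
    if len(panels) < 2:
        raise InsufficientTargetsError(
            f"insufficient targets: need >= 2 panels, got {len(panels)}")
    dns = [panel_digital_numbers(stack, p, statistic) for p in panels]

    gain, offset, residual = {}, {}, {}
    for role in stack.bands:
        refl = np.array([p.known_reflectance[role] for p in panels])
        dn = np.array([d[role] for d in dns])
        if np.ptp(refl) == 0 or np.ptp(dn) == 0:
            raise SingularFitError(
                f"band {role!r}: panels do not span distinct reflectances/DNs")
        g, o = np.polyfit(dn, refl, 1)
        gain[role], offset[role] = float(g), float(o)
        residual[role] = float(np.sqrt(np.mean((g * dn + o - refl) ** 2)))
    return LinearCalibration(gain=gain, offset=offset,
                             n_targets=len(panels), residual=residual)


def apply_elc(stack: BandStack, cal: LinearCalibration) -> BandStack:
    """Convert a DN stack to reflectance, clipping to [0, 1] with a logged count.

    Stacks already in reflectance are passed through unchanged (pre-calibrated
    orthomosaics are valid input further down the pipeline).
    """
    if stack.value_domain == REFLECTANCE:
        log.info("stack already in reflectance; calibration bypassed")
        return stack
    bands = {}
    for role, grid in stack.bands.items():
        if role not in cal.gain:
            raise KeyError(f"no calibration entry for band {role!r}")
        raw = cal.gain[role] * grid + cal.offset[role]
        clipped = int(np.sum((raw < 0) | (raw > 1)))
        if clipped:
            log.info("band %s: %d pixels clipped to [0, 1]", role, clipped)
        bands[role] = np.clip(raw, 0.0, 1.0)
    return BandStack(bands=bands, transform=stack.transform, crs=stack.crs,
                     nodata=None, value_domain=REFLECTANCE)
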