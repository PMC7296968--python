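"""The eight normalized-difference vegetation indices.

Every index has the form (a - b) / (a + b) for an ordered band pair (a, b),
so finite values always lie in [-1, 1] and swapping the bands negates the
index. Zero-denominator pixels are NaN (excluded downstream), never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import REFLECTANCE, BandStack
from .segmentation import CanopyMask

#: index name -> (numerator-leading band a, band b); value = (a-b)/(a+b)
INDEX_REGISTRY: dict[str, tuple[str, str]] = {
    "NDRE": ("nir", "rededge"),    # normalized difference red-edge
    "NDVI": ("nir", "red"),        # normalized difference vegetation index
    "GNDVI": ("nir", "green"),     # green NDVI
    "BNDVI": ("nir", "blue"),      # blue NDVI
    "NDREI": ("rededge", "red"),   # red-edge / red normalized difference
    "NPCI": ("rededge", "blue"),   # normalized pigment chlorophyll index
    "GRVI": ("green", "red"),      # green-red vegetation index
    "NGBDI": ("green", "blue"),    # normalized green-blue difference index
}

INDEX_NAMES = tuple(INDEX_REGISTRY)


def list_indices() -> list[tuple[str, str, str]]:
    """Registry as (name, band_a, band_b) triples, in canonical order."""
    return [(name, a, b) for name, (a, b) in INDEX_REGISTRY.items()]


@dataclass
class IndexRaster:
    name: str
    values: np.ndarray
    valid: np.ndarray  # False where values is NaN


def normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (a - b) / denom
    return np.where(denom == 0, np.nan, out)


def compute_index(stack: BandStack, name: str,
                  mask: CanopyMask | None = None) -> IndexRaster:
    """Per-pixel index raster, optionally restricted to canopy pixels."""
    if stack.value_domain != REFLECTANCE:
        raise ValueError("vegetation indices require reflectance values")
    if name not in INDEX_REGISTRY:
        raise KeyError(f"unknown index {name!r}; known: {sorted(INDEX_REGISTRY)}")
    role_a, role_b = INDEX_REGISTRY[name]
    values = normalized_difference(stack.bands[role_a], stack.bands[role_b])
    if mask is not None:
        values = np.where(mask.mask == 1, values, np.nan)
    return IndexRaster(name=name, values=values, valid=np.isfinite(values))
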