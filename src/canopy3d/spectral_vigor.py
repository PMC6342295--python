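"""NDVI map algebra and per-tree spectral/vigour traits.

NDVI = (NIR − RED)/(NIR + RED) computed pixelwise on reflectance
rasters; per-tree vigour is the mean NDVI over a crown footprint.  The
SPAD optical greenness index converts to total chlorophyll a+b
concentration (µg cm⁻²) through the leaf calibration line
Cab = 0.8271·SPAD − 12.8.

Band convention: NIR is the 760–900 nm band, RED the 630–690 nm band
(the physically consistent assignment).  Inputs are assumed to already
be reflectances in [0, 1]; no radiometric calibration is applied.
"""

from __future__ import annotations

import warnings

import numpy as np

from .crown_segmentation import CrownSegment
from .raster_io import RasterGrid

SPAD_TO_CAB_SLOPE = 0.8271
SPAD_TO_CAB_INTERCEPT = -12.8


def ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """Pixelwise (NIR − RED)/(NIR + RED); zero-sum pixels become nodata."""
    nir.require_aligned(red, "NIR and RED")
    n, r = nir.values, red.values
    denom = n + r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (n - r) / denom
    out = np.where(denom == 0, np.nan, out)
    return nir.like(out, units="ndvi")


def per_tree_ndvi(ndvi_grid: RasterGrid, segment: CrownSegment) -> float:
    """Mean NDVI over the crown footprint, ignoring nodata pixels."""
    vals = ndvi_grid.values[segment.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"segment {segment.label}: no valid NDVI pixels")
    return float(vals.mean())


def spad_to_cab(spad):
    """Chlorophyll a+b (µg cm⁻²) from a SPAD reading.

    Negative outputs (SPAD below ~15.5) are outside the calibration
    domain; they are returned as-is with a warning.
    """
    spad = np.asarray(spad, dtype=float)
    if np.any(spad < 0):
        raise ValueError("SPAD readings must be ≥ 0")
    cab = SPAD_TO_CAB_SLOPE * spad + SPAD_TO_CAB_INTERCEPT
    if np.any(cab < 0):
        warnings.warn(
            "SPAD below the calibration domain: negative Cab returned",
            stacklevel=2)
    return float(cab) if cab.ndim == 0 else cab
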