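"""Per-tree geometric traits from the nDSM, plus the field-method formulas.

The raster route integrates canopy volume per pixel: each canopy pixel
contributes its area times its height above ground (nDSM value), summed
over the crown footprint; the prism between the ground and the lowest
canopy (clearance d, either the orchard mean 0.7 m or a per-tree
measurement) is subtracted to give the net canopy volume.

The manual field route models the crown as an ellipsoid with diameters
D1 and D2, top at tree height Ht and base at the lowest-canopy height
Hb:

    V = (4π/3) · (D1/2) · (D2/2) · ((Ht − Hb)/2)

For a solid half-ellipsoid upper surface, per-pixel integration
converges to (5/3)πabc = 1.25 × the ellipsoid value — the raster route
measures the volume under the visible surface down to the crown base,
not the ellipsoid.  Where the crown has an empty vase core the raster
route falls below the ellipsoid figure, which the field method cannot
detect.

Tree height is the crown's maximum surface elevation minus the mean
terrain elevation in an annulus around it; crown diameter is the
equivalent-circle diameter of the projected footprint area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from .crown_segmentation import CrownSegment
from .raster_io import RasterGrid

logger = logging.getLogger("canopy3d")


# --------------------------------------------------------------------------
# field-method closed forms
# --------------------------------------------------------------------------

def ellipsoid_volume(d1: float, d2: float, ht: float, hb: float) -> float:
    """Ellipsoid-method crown volume (m³) from field measurements.

    (4π/3)·(D1/2)·(D2/2)·((Ht−Hb)/2), with D1/D2 the crown diameters,
    Ht the tree height and Hb the lowest canopy height.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("crown diameters must be positive")
    if ht <= hb:
        raise ValueError(f"tree height {ht} must exceed canopy base {hb}")
    return (4.0 * np.pi / 3.0) * (d1 / 2.0) * (d2 / 2.0) * ((ht - hb) / 2.0)


def tcsa(circumference: float) -> float:
    """Trunk cross-sectional area (m²) from circumference: C²/(4π)."""
    if circumference <= 0:
        raise ValueError("trunk circumference must be positive")
    return circumference**2 / (4.0 * np.pi)


# --------------------------------------------------------------------------
# raster-route traits
# --------------------------------------------------------------------------

def tree_height(dsm: RasterGrid, dtm: RasterGrid, segment: CrownSegment,
                ring_width: float = 2.0,
                exclude_mask: np.ndarray | None = None) -> float:
    """Crown apex elevation minus the surrounding terrain elevation.

    The terrain reference is the mean DTM over an annulus ``ring_width``
    metres wide around the segment; ``exclude_mask`` (typically the
    union of all crown masks) removes canopy pixels from the annulus.
    """
    dsm.require_aligned(dtm, "DSM and DTM")
    seg_vals = dsm.values[segment.mask]
    apex = np.nanmax(seg_vals)
    ring_px = max(int(round(ring_width / dsm.pixel_size_x)), 1)
    ring = binary_dilation(segment.mask, iterations=ring_px)
    ring &= ~(segment.mask if exclude_mask is None else (exclude_mask | segment.mask))
    ring &= dtm.valid_mask
    if not ring.any():
        raise ValueError(
            f"segment {segment.label}: empty terrain annulus "
            f"(ring_width={ring_width} m)")
    terrain_ref = float(np.mean(dtm.values[ring]))
    return float(apex - terrain_ref)


def crown_diameter(segment: CrownSegment) -> float:
    """Equivalent-circle diameter (m): 2·sqrt(area/π)."""
    if segment.footprint_area <= 0:
        raise ValueError("segment has zero footprint area")
    return 2.0 * np.sqrt(segment.footprint_area / np.pi)


def total_volume(ndsm: RasterGrid, segment: CrownSegment) -> float:
    """Ground-to-surface volume (m³): Σ pixel_area × nDSM over the crown."""
    vals = ndsm.values[segment.mask]
    bad = ~np.isfinite(vals)
    if bad.any():
        logger.warning("segment %d: %d nodata pixel(s) excluded from volume",
                       segment.label, int(bad.sum()))
        vals = vals[~bad]
    if vals.size == 0:
        return 0.0
    return float(vals.sum() * ndsm.pixel_area)


def below_canopy_volume(segment: CrownSegment, d: float) -> float:
    """Prism between ground and the lowest canopy: footprint area × d."""
    if d < 0:
        raise ValueError("canopy clearance d must be ≥ 0")
    return segment.footprint_area * d


def net_canopy_volume(total: float, below: float) -> float:
    """Net canopy volume: max(total − below, 0); clamping is logged."""
    if total < 0 or below < 0:
        raise ValueError("volumes must be ≥ 0")
    if below > total:
        warnings.warn(
            f"below-canopy volume {below:.3f} m³ exceeds total "
            f"{total:.3f} m³; net clamped to 0", stacklevel=2)
        return 0.0
    return total - below


@dataclass
class TreeMetrics:
    """Estimated per-tree traits from the raster route."""

    tree_id: int
    height: float
    diameter: float
    projected_area: float
    total_volume: float
    below_canopy_volume: float
    net_canopy_volume: float
    mean_ndvi: float = np.nan


def compute_tree_metrics(dsm: RasterGrid, dtm: RasterGrid, ndsm: RasterGrid,
                         segments: list[CrownSegment],
                         d: float = 0.7,
                         d_table: dict[int, float] | None = None,
                         ring_width: float = 2.0) -> list[TreeMetrics]:
    """All geometric traits for every segment.

    Clearance mode: with ``d_table`` (tree_id → measured d) each tree
    uses its own clearance; otherwise the fixed orchard mean ``d`` is
    used for all.  A tree missing from ``d_table`` is an error.
    """
    all_crowns = np.zeros(ndsm.shape, dtype=bool)
    for seg in segments:
        all_crowns |= seg.mask
    out = []
    for seg in segments:
        if d_table is not None:
            if seg.label not in d_table:
                raise KeyError(
                    f"tree_id {seg.label} missing from the clearance table")
            d_i = d_table[seg.label]
        else:
            d_i = d
        tot = total_volume(ndsm, seg)
        below = below_canopy_volume(seg, d_i)
        out.append(TreeMetrics(
            tree_id=seg.label,
            height=tree_height(dsm, dtm, seg, ring_width, exclude_mask=all_crowns),
            diameter=crown_diameter(seg),
            projected_area=seg.footprint_area,
            total_volume=tot,
            below_canopy_volume=below,
            net_canopy_volume=net_canopy_volume(tot, below),
        ))
    return out


def metrics_frame(metrics: list[TreeMetrics]) -> pd.DataFrame:
    """Tidy per-tree table (the metrics.csv layout)."""
    return pd.DataFrame([{
        "tree_id": m.tree_id,
        "height_m": m.height,
        "diameter_m": m.diameter,
        "projected_area_m2": m.projected_area,
        "total_volume_m3": m.total_volume,
        "below_volume_m3": m.below_canopy_volume,
        "net_volume_m3": m.net_canopy_volume,
        "mean_ndvi": m.mean_ndvi,
    } for m in metrics])
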