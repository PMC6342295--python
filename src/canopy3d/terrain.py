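"""Terrain modelling: ground-point sampling, DTM triangulation, nDSM.

The bare-terrain model is rebuilt from the DSM itself, mimicking the
GIS workflow of triangulating points placed in the inter-row and
intra-row ground zones of an orchard: ground points are sampled on a
regular grid restricted to non-canopy pixels, Delaunay-triangulated,
linearly interpolated onto the DSM grid, and subtracted from the DSM to
give the normalized surface model (canopy height model).

Canopy pixels are excluded either by a caller-supplied mask or by a
provisional height rule: DSM minus a coarse per-block median exceeds
0.5 m, dilated by a few pixels.  Each ground sample takes a low
percentile of the elevations in its neighbourhood, which is robust to
stray low vegetation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.ndimage import binary_dilation
from scipy.spatial import QhullError

from .raster_io import RasterGrid

logger = logging.getLogger("canopy3d")


@dataclass
class GroundPointSet:
    """Sampled (x, y, z) bare-ground points in world metres."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z must have equal shape")
        if self.x.size < 3:
            raise ValueError("need at least 3 ground points")

    def __len__(self) -> int:
        return self.x.size


def _block_median_surface(values: np.ndarray, block: int) -> np.ndarray:
    """Per-block median, upsampled back to full size (edge blocks partial)."""
    nr, nc = values.shape
    out = np.empty_like(values)
    for r0 in range(0, nr, block):
        for c0 in range(0, nc, block):
            r1, c1 = min(r0 + block, nr), min(c0 + block, nc)
            blk = values[r0:r1, c0:c1]
            finite = blk[np.isfinite(blk)]
            out[r0:r1, c0:c1] = np.median(finite) if finite.size else np.nan
    return out


def provisional_canopy_mask(dsm: RasterGrid, block_m: float = 5.0,
                            height_cut: float = 0.5,
                            dilate_px: int = 3) -> np.ndarray:
    """Height-above-coarse-median rule for flagging canopy pixels.

    ``block_m`` should be at least the tree spacing so every block keeps
    a ground majority and the block median tracks the terrain.
    """
    block = max(int(round(block_m / dsm.pixel_size_x)), 1)
    coarse = _block_median_surface(dsm.values, block)
    mask = (dsm.values - coarse) > height_cut
    if dilate_px > 0:
        mask = binary_dilation(mask, iterations=dilate_px)
    return mask


def sample_ground_points(dsm: RasterGrid,
                         exclusion_mask: np.ndarray | None = None,
                         grid_step: float = 2.5,
                         percentile: float = 10.0) -> GroundPointSet:
    """Sample bare-ground elevations on a regular grid of ``grid_step`` m.

    Within each grid cell the sample takes the ``percentile``-th
    elevation among non-excluded pixels and is placed at the pixel whose
    elevation is closest to that value.
    """
    if exclusion_mask is None:
        exclusion_mask = provisional_canopy_mask(dsm)
    if exclusion_mask.shape != dsm.shape:
        raise ValueError("exclusion_mask must align with the DSM")
    usable = dsm.valid_mask & ~exclusion_mask

    step_px = max(int(round(grid_step / dsm.pixel_size_x)), 1)
    nr, nc = dsm.shape
    xs, ys, zs = [], [], []
    for r0 in range(0, nr, step_px):
        for c0 in range(0, nc, step_px):
            r1, c1 = min(r0 + step_px, nr), min(c0 + step_px, nc)
            sel = usable[r0:r1, c0:c1]
            if not sel.any():
                continue
            vals = dsm.values[r0:r1, c0:c1][sel]
            z = np.percentile(vals, percentile)
            # place the sample at the pixel realizing (closest to) z
            rr, cc = np.nonzero(sel)
            k = int(np.argmin(np.abs(vals - z)))
            x, y = dsm.xy(r0 + rr[k], c0 + cc[k])
            xs.append(float(x))
            ys.append(float(y))
            zs.append(float(vals[k]))
    if len(xs) < 3:
        raise ValueError(
            f"only {len(xs)} usable ground points (need ≥ 3); "
            "exclusion mask too aggressive or grid_step too large")
    return GroundPointSet(np.array(xs), np.array(ys), np.array(zs))


def build_dtm(points: GroundPointSet, template: RasterGrid) -> RasterGrid:
    """Rasterize a piecewise-linear (Delaunay) terrain model.

    Inside the convex hull of the points the DTM is the linear
    interpolant over the Delaunay triangulation; outside, the nearest
    point's elevation is used.  The output shares ``template``'s grid.
    """
    pts = np.column_stack([points.x, points.y])
    try:
        lin = LinearNDInterpolator(pts, points.z)
    except QhullError as exc:
        raise ValueError("ground points are degenerate (collinear)") from exc
    X, Y = template.cell_centers()
    z = lin(X, Y)
    hole = ~np.isfinite(z)
    if hole.any():
        near = NearestNDInterpolator(pts, points.z)
        z[hole] = near(X[hole], Y[hole])
    return template.like(z, units="m")


def compute_ndsm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Normalized surface model: DSM − DTM, negatives clamped to 0.

    Heights below the terrain model are interpolation noise, physically
    meaningless, and would corrupt volume sums; they are clamped.
    Nodata in either input propagates.
    """
    dsm.require_aligned(dtm, "DSM and DTM")
    diff = dsm.values - dtm.values
    n_neg = int(np.sum(diff < 0))
    if n_neg:
        logger.debug("nDSM: clamped %d negative cells to 0", n_neg)
    out = np.where(np.isfinite(diff), np.maximum(diff, 0.0), np.nan)
    return dsm.like(out, units="m")
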