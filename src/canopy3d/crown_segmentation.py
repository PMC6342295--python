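"""Individual crown delineation by local adaptive thresholding.

Crowns are separated from the ground on the normalized surface model
(nDSM) by Niblack's or Sauvola–Pietikäinen's local thresholding (or a
plain fixed height cut), then labelled as 8-connected components with a
minimum-footprint filter.  On grid-planted orchards with non-touching
crowns this delineates every tree without watershed splitting.

Thresholding decisions (value strictly greater than the local
threshold; equality is background) use the mean and standard deviation
over the window *clipped at the raster border* — edge pixels see a
smaller window rather than reflected or padded values.  Local moments
come from integral images, so cost is independent of window size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .raster_io import RasterGrid


@dataclass
class SegmentationParams:
    """Thresholding method and component-filter settings.

    window defaults to about 1.5 × the expected crown diameter in
    pixels (computed from the grid when left as None).  k defaults to
    −0.2 for Niblack and 0.5 for Sauvola, the standard parameter
    choices for the two methods; Sauvola's dynamic range r defaults to
    half the value range of the grid.
    """

    method: str = "sauvola"
    window: int | None = None
    k: float | None = None
    r: float | None = None
    height_threshold: float = 0.5     # m; fixed method
    min_area: float = 0.5             # m²
    expected_crown_diameter: float = 3.0  # m; sets the auto window

    def __post_init__(self) -> None:
        if self.method not in ("niblack", "sauvola", "fixed"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.window is not None and (self.window < 3 or self.window % 2 == 0):
            raise ValueError("window must be an odd integer ≥ 3")
        if self.min_area <= 0:
            raise ValueError("min_area must be positive")

    def resolved_window(self, grid: RasterGrid) -> int:
        if self.window is not None:
            return self.window
        w = int(round(1.5 * self.expected_crown_diameter / grid.pixel_size_x))
        return max(w | 1, 3)  # force odd

    def resolved_k(self) -> float:
        if self.k is not None:
            return self.k
        return -0.2 if self.method == "niblack" else 0.5


def local_mean_std(values: np.ndarray, window: int):
    """Mean and sd over the border-clipped window centred at each pixel.

    Integral-image implementation; normalization uses the actual number
    of in-bounds pixels, so edge statistics are unbiased.
    """
    v = np.asarray(values, dtype=float)
    nr, nc = v.shape
    h = window // 2
    s1 = np.zeros((nr + 1, nc + 1))
    s2 = np.zeros((nr + 1, nc + 1))
    np.cumsum(np.cumsum(v, axis=0), axis=1, out=s1[1:, 1:])
    np.cumsum(np.cumsum(v * v, axis=0), axis=1, out=s2[1:, 1:])
    r0 = np.clip(np.arange(nr) - h, 0, nr)
    r1 = np.clip(np.arange(nr) + h + 1, 0, nr)
    c0 = np.clip(np.arange(nc) - h, 0, nc)
    c1 = np.clip(np.arange(nc) + h + 1, 0, nc)
    cnt = (r1 - r0)[:, None] * (c1 - c0)[None, :]

    def box(s):
        return (s[np.ix_(r1, c1)] - s[np.ix_(r0, c1)]
                - s[np.ix_(r1, c0)] + s[np.ix_(r0, c0)])

    mean = box(s1) / cnt
    var = np.maximum(box(s2) / cnt - mean * mean, 0.0)
    return mean, np.sqrt(var)


def local_threshold(grid: RasterGrid, params: SegmentationParams) -> np.ndarray:
    """Binary foreground mask of ``grid`` under ``params``.

    Niblack: value > m + k·s.  Sauvola: value > m·(1 + k·(s/r − 1)).
    Fixed: value > height_threshold.  Nodata is always background.
    """
    valid = grid.valid_mask
    v = np.where(valid, grid.values, 0.0)

    if params.method == "fixed":
        mask = v > params.height_threshold
        return mask & valid

    window = params.resolved_window(grid)
    if window > max(grid.shape):
        raise ValueError(
            f"window {window} exceeds grid size {grid.shape}")
    k = params.resolved_k()
    mean, sd = local_mean_std(v, window)
    if params.method == "niblack":
        thresh = mean + k * sd
    else:  # sauvola
        r = params.r
        if r is None:
            vr = v[valid]
            r = (vr.max() - vr.min()) / 2.0 if vr.size else 1.0
            if r <= 0:
                r = 1.0
        thresh = mean * (1.0 + k * (sd / r - 1.0))
    return (v > thresh) & valid


@dataclass
class CrownSegment:
    """One delineated crown: full-frame boolean mask plus summaries."""

    label: int
    mask: np.ndarray
    footprint_area: float          # m²
    centroid_x: float              # m, world
    centroid_y: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def label_crowns(mask: np.ndarray, grid: RasterGrid,
                 params: SegmentationParams | None = None) -> list[CrownSegment]:
    """8-connected components of ``mask``, filtered and ordered.

    Components smaller than ``params.min_area`` (m²) are discarded.
    Labels are assigned 1..n in raster-scan order of each component's
    top-left pixel (smallest row, then smallest column in that row).
    """
    params = params or SegmentationParams()
    lab = cc_label(mask, connectivity=2)
    segments = []
    for rp in regionprops(lab):
        area = rp.num_pixels * grid.pixel_area
        if area < params.min_area:
            continue
        coords = rp.coords
        top = coords[np.lexsort((coords[:, 1], coords[:, 0]))][0]
        full = np.zeros(mask.shape, dtype=bool)
        full[coords[:, 0], coords[:, 1]] = True
        cx, cy = grid.xy(rp.centroid[0], rp.centroid[1])
        segments.append((tuple(top), CrownSegment(
            label=0, mask=full, footprint_area=area,
            centroid_x=float(cx), centroid_y=float(cy),
            bbox=tuple(rp.bbox))))
    segments.sort(key=lambda item: item[0])
    out = []
    for i, (_, seg) in enumerate(segments, start=1):
        seg.label = i
        out.append(seg)
    return out


def segments_from_labels(labels: np.ndarray, grid: RasterGrid) -> list[CrownSegment]:
    """Rebuild CrownSegment objects from a labelled integer raster."""
    out = []
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        mask = labels == lab
        rows, cols = np.nonzero(mask)
        cx, cy = grid.xy(rows.mean(), cols.mean())
        out.append(CrownSegment(
            label=int(lab), mask=mask,
            footprint_area=float(mask.sum() * grid.pixel_area),
            centroid_x=float(cx), centroid_y=float(cy),
            bbox=(int(rows.min()), int(cols.min()),
                  int(rows.max()) + 1, int(cols.max()) + 1)))
    return out


def segment_crowns(ndsm: RasterGrid,
                   params: SegmentationParams | None = None) -> list[CrownSegment]:
    """Threshold the nDSM and label crowns in one step."""
    params = params or SegmentationParams()
    return label_crowns(local_threshold(ndsm, params), ndsm, params)


@dataclass
class MatchResult:
    """One-to-one pairing between segments and truth/field trees."""

    pairs: list[tuple[CrownSegment, object, float]]
    unmatched_segments: list[CrownSegment]
    unmatched_trees: list[object]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def match_segments_to_truth(segments, trees, max_dist: float = 2.5) -> MatchResult:
    """Greedy nearest-centroid one-to-one pairing within ``max_dist`` m.

    Candidate pairs are taken in order of increasing distance; ties are
    broken deterministically by segment label, then tree order.
    """
    candidates = []
    for si, seg in enumerate(segments):
        for ti, tree in enumerate(trees):
            d = float(np.hypot(seg.centroid_x - tree.x,
                               seg.centroid_y - tree.y))
            if d <= max_dist:
                candidates.append((d, seg.label, ti, si))
    candidates.sort()
    used_s, used_t = set(), set()
    pairs = []
    for d, _lab, ti, si in candidates:
        if si in used_s or ti in used_t:
            continue
        used_s.add(si)
        used_t.add(ti)
        pairs.append((segments[si], trees[ti], d))
    return MatchResult(
        pairs=pairs,
        unmatched_segments=[s for i, s in enumerate(segments) if i not in used_s],
        unmatched_trees=[t for i, t in enumerate(trees) if i not in used_t],
    )
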