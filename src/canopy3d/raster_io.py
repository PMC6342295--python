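"""Georeferenced raster grid model and GeoTIFF / CSV input-output.

All spatial data in the package travels as :class:`RasterGrid`: a 2-D
float array in a projected, metre-unit coordinate system with a north-up
affine transform and explicit nodata semantics.  In memory nodata cells
are held as NaN; on disk they are stored as the grid's nodata sentinel.

The coordinate convention is pixel-centre sampling on a north-up grid:
row 0 is the northernmost row, the world coordinate of pixel ``(row, col)``
is the centre of its cell.  All lengths are metres, areas m², volumes m³.

GeoTIFF reading/writing is built on :mod:`tifffile`, carrying the minimal
set of GeoTIFF tags (pixel scale, tie point, geo-key directory for the
model type and linear unit, and a GDAL-style nodata string).  Geographic
(degree-unit) files are rejected: every downstream computation multiplies
pixel sizes into areas and volumes, which is only meaningful in metres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger("canopy3d")

# GeoTIFF tag ids
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids / values
_KEY_MODEL_TYPE = 1024          # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025         # 1 = PixelIsArea
_KEY_PROJ_LINEAR_UNITS = 3076   # 9001 = metre
_UNIT_METRE = 9001

DEFAULT_NODATA = -9999.0


class RasterAlignmentError(ValueError):
    """Raised when two grids that must share a common grid do not."""


@dataclass
class RasterGrid:
    """A single-band georeferenced raster in a projected metric CRS.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; NaN marks nodata.
    x_origin, y_origin : float
        World coordinates (m) of the **outer corner** of pixel (0, 0),
        i.e. the north-west corner of the raster.
    pixel_size_x, pixel_size_y : float
        Cell size in metres (both positive; the grid is north-up, so
        world y decreases with increasing row).
    nodata : float
        Sentinel written to disk for NaN cells.
    units : str
        Free-text label for the cell values ("m", "reflectance", "ndvi").
    """

    values: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    pixel_size_x: float = 1.0
    pixel_size_y: float = 1.0
    nodata: float = DEFAULT_NODATA
    units: str = "m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise ValueError("pixel sizes must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area(self) -> float:
        """Area of one cell in m²."""
        return self.pixel_size_x * self.pixel_size_y

    def xy(self, row, col):
        """World coordinates (m) of the centre of pixel ``(row, col)``."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.pixel_size_x
        y = self.y_origin - (np.asarray(row) + 0.5) * self.pixel_size_y
        return x, y

    def rowcol(self, x, y):
        """Pixel indices containing world point ``(x, y)`` (floor rule)."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.pixel_size_x).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.pixel_size_y).astype(int)
        return row, col

    def cell_centers(self):
        """Meshgrid arrays (X, Y) of all pixel-centre coordinates."""
        nr, nc = self.shape
        xs = self.x_origin + (np.arange(nc) + 0.5) * self.pixel_size_x
        ys = self.y_origin - (np.arange(nr) + 0.5) * self.pixel_size_y
        return np.meshgrid(xs, ys)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the raster's outer edges."""
        nr, nc = self.shape
        return (
            self.x_origin,
            self.x_origin + nc * self.pixel_size_x,
            self.y_origin - nr * self.pixel_size_y,
            self.y_origin,
        )

    # -- semantics --------------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.pixel_size_x - other.pixel_size_x) <= tol
            and abs(self.pixel_size_y - other.pixel_size_y) <= tol
        )

    def require_aligned(self, other: "RasterGrid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise RasterAlignmentError(
                f"{what} are not aligned: shapes {self.shape} vs {other.shape}, "
                f"origins ({self.x_origin}, {self.y_origin}) vs "
                f"({other.x_origin}, {other.y_origin})"
            )

    def like(self, values: np.ndarray, units: str | None = None) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)


def _geokey_directory(projected: bool = True, metre: bool = True) -> tuple:
    unit = _UNIT_METRE if metre else 9102  # 9102 = degree
    keys = [
        (_KEY_MODEL_TYPE, 0, 1, 1 if projected else 2),
        (_KEY_RASTER_TYPE, 0, 1, 1),
        (_KEY_PROJ_LINEAR_UNITS, 0, 1, unit),
    ]
    header = (1, 1, 0, len(keys))
    flat = list(header)
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def write_raster(grid: RasterGrid, path, *, projected: bool = True,
                 metre_units: bool = True) -> None:
    """Write ``grid`` as a single-band float32 GeoTIFF with nodata.

    ``projected``/``metre_units`` exist to write deliberately malformed
    fixtures (geographic CRS) for testing; real outputs always use the
    defaults.
    """
    data = grid.values.astype(np.float32)
    invalid = ~np.isfinite(data)
    if invalid.all():
        warnings.warn("writing an all-nodata raster", stacklevel=2)
        logger.warning("raster %s contains only nodata", path)
    data = np.where(invalid, np.float32(grid.nodata), data)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (float(grid.pixel_size_x), float(grid.pixel_size_y), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(grid.x_origin), float(grid.y_origin), 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", 16,
         _geokey_directory(projected=projected, metre=metre_units)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags,
                     metadata=None, photometric="minisblack")


def _parse_geokeys(raw) -> dict[int, int]:
    vals = list(raw)
    n = vals[3]
    out = {}
    for i in range(n):
        key_id, _loc, _count, value = vals[4 + 4 * i: 8 + 4 * i]
        out[key_id] = value
    return out


def read_raster(path, band: int | None = None, units: str = "m") -> RasterGrid:
    """Read a single-band GeoTIFF in a projected metric CRS.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        Geographic (degree) CRS, or a multi-band file without ``band``.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray(), dtype=float)
        if data.ndim == 3:
            if band is None:
                raise ValueError(
                    f"{path}: multi-band file; pass band= to select one"
                )
            data = data[..., band] if data.shape[-1] < data.shape[0] else data[band]
        elif len(tif.pages) > 1:
            if band is None:
                raise ValueError(
                    f"{path}: multi-page file; pass band= to select one"
                )
            data = np.asarray(tif.pages[band].asarray(), dtype=float)
            page = tif.pages[band]
        tags = page.tags

        geo = tags.get(_TAG_GEO_KEY_DIRECTORY)
        if geo is not None:
            keys = _parse_geokeys(geo.value)
            if keys.get(_KEY_MODEL_TYPE) == 2:
                raise ValueError(
                    f"{path}: geographic (degree-unit) CRS; a projected "
                    "metric CRS is required"
                )
            unit = keys.get(_KEY_PROJ_LINEAR_UNITS, _UNIT_METRE)
            if unit != _UNIT_METRE:
                raise ValueError(
                    f"{path}: linear unit code {unit} is not metre (9001)"
                )

        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie = tags.get(_TAG_MODEL_TIEPOINT)
        psx, psy = (1.0, 1.0) if scale is None else (scale.value[0], scale.value[1])
        x0, y0 = (0.0, 0.0) if tie is None else (tie.value[3], tie.value[4])

        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = DEFAULT_NODATA if nodata_tag is None else float(nodata_tag.value)

    values = np.where(np.isclose(data, nodata, equal_nan=False), np.nan, data)
    values[~np.isfinite(data)] = np.nan
    return RasterGrid(values=values, x_origin=x0, y_origin=y0,
                      pixel_size_x=psx, pixel_size_y=psy,
                      nodata=nodata, units=units)
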