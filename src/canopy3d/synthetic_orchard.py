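"""Seeded synthetic orchard scenes with per-tree analytic ground truth.

The generator emulates a mature, grid-planted olive orchard (5 × 5 m
spacing) on gently varying terrain, seen by a nadir camera: it renders a
DSM (terrain + crown upper surfaces), the true DTM, and NIR/RED
reflectance bands, together with a truth table of per-tree geometry
(crown diameters D1/D2, tree height Ht, lowest-canopy height Hb) and
vigour (LAI, SPAD).  Every downstream stage — terrain modelling, crown
segmentation, geometric traits, spectral traits, water-status analysis —
is testable against this truth without any field campaign.

Crown model
-----------
Each crown is the upper half of an ellipsoid with semi-axes
a = D1/2, b = D2/2, c = (Ht − Hb)/2, its equator at terrain + Hb + c,
so the apex sits at terrain + Ht.  The nadir-visible surface over the
footprint is

    z_top(x, y) = terrain + Hb + c + c·sqrt(1 − (Δx/a)² − (Δy/b)²).

Two closed forms anchor the truth table:

* ellipsoid (field) volume  V_e = (4π/3)·a·b·c — what the manual
  ellipsoid method reports;
* surface-integral volume   V_s = ∫(z_top − Hb) dA = πabc + (2/3)πabc
  = (5/3)πabc = (5/4)·V_e — what per-pixel integration of a perfect
  upper surface converges to.

Vase-trained olives have an empty central core; the generator models it
as a conical depression of the upper surface (radius fraction f of the
footprint, apex depth f·(Ht − Hb)), removing (2/3)πabc·f³ from V_s.

Reflectance model
-----------------
Canopy NDVI increases linearly with LAI from 0.30 to 0.70 over the
configured LAI range; soil NDVI sits near 0.10.  NIR and RED are
back-solved from NDVI with NIR + RED fixed at 0.6, plus Gaussian noise.

Stem water potential fixtures emulate two irrigation regimes: irrigated
trees fluctuate in roughly [−2.2, −1.4] MPa; rainfed trees decline
toward −4.5 MPa with a mid-season rain recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .canopy_geometry import ellipsoid_volume
from .raster_io import RasterGrid, write_raster
from .water_status import SWPSeries


@dataclass
class SceneConfig:
    """Layout, terrain, crown and reflectance parameters of a scene.

    Defaults reproduce the study conditions: a 3 × 5-tree block planted
    on a 5 × 5 m grid, tree heights 2.1–3.9 m, ground clearance Hb
    around 0.7 m, 2 cm ground sample distance, canopy NDVI 0.30–0.70.
    """

    rows: int = 3
    cols: int = 5
    tree_spacing_x: float = 5.0
    tree_spacing_y: float = 5.0
    gsd: float = 0.02                      # m per pixel
    margin: float = 0.0                    # extra ground beyond the grid, m
    terrain_z0: float = 100.0
    terrain_gradient: tuple[float, float] = (0.01, 0.005)   # m/m in x, y
    terrain_noise_amplitude: float = 0.15  # m, smooth undulation
    terrain_noise_wavelength: float = 15.0  # m, control-point spacing
    d1_range: tuple[float, float] = (2.2, 3.6)
    d2_range: tuple[float, float] = (2.2, 3.6)
    ht_range: tuple[float, float] = (2.1, 3.9)
    hb_mean: float = 0.7
    hb_sd: float = 0.05
    hollow_core_fraction: float = 0.0      # [0, 1): vase-core radius/depth fraction
    lai_range: tuple[float, float] = (0.5, 2.5)
    soil_ndvi: float = 0.10
    ndvi_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")
        if not (0 <= self.hollow_core_fraction < 1):
            raise ValueError("hollow_core_fraction must be in [0, 1)")
        min_spacing = min(self.tree_spacing_x, self.tree_spacing_y)
        if max(self.d1_range[1], self.d2_range[1]) >= min_spacing:
            raise ValueError(
                "crown diameter range exceeds tree spacing: crowns would overlap"
            )
        if self.hb_mean >= self.ht_range[0]:
            raise ValueError("hb_mean must lie below the minimum tree height")

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the scene in metres."""
        return (
            self.cols * self.tree_spacing_x + 2 * self.margin,
            self.rows * self.tree_spacing_y + 2 * self.margin,
        )


@dataclass
class TreeTruth:
    """Analytic ground truth for one synthetic tree."""

    tree_id: int
    x: float
    y: float
    d1: float
    d2: float
    ht: float
    hb: float
    lai_true: float
    spad_true: float
    ndvi_true: float
    hollow_core_fraction: float = 0.0

    @property
    def d(self) -> float:
        """Canopy-to-ground clearance used for the below-canopy prism."""
        return self.hb

    @property
    def semi_axes(self) -> tuple[float, float, float]:
        return self.d1 / 2.0, self.d2 / 2.0, (self.ht - self.hb) / 2.0

    @property
    def ellipsoid_vol(self) -> float:
        """Field ellipsoid-method volume, (4π/3)·a·b·c."""
        return ellipsoid_volume(self.d1, self.d2, self.ht, self.hb)

    @property
    def surface_integral_vol(self) -> float:
        """Analytic ∫(z_top − Hb) dA: (5/3)πabc minus the vase core."""
        a, b, c = self.semi_axes
        solid = (5.0 / 3.0) * np.pi * a * b * c
        f = self.hollow_core_fraction
        return solid - (2.0 / 3.0) * np.pi * a * b * c * f**3


@dataclass
class OrchardScene:
    """Rendered rasters plus the truth table they were rendered from."""

    config: SceneConfig
    dsm: RasterGrid
    dtm_true: RasterGrid
    nir: RasterGrid
    red: RasterGrid
    trees: list[TreeTruth] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trees:
            rows.append({
                "tree_id": t.tree_id, "x": t.x, "y": t.y,
                "d1": t.d1, "d2": t.d2, "ht": t.ht, "hb": t.hb, "d": t.d,
                "lai_true": t.lai_true, "spad_true": t.spad_true,
                "ndvi_true": t.ndvi_true,
                "ellipsoid_volume": t.ellipsoid_vol,
                "surface_integral_volume": t.surface_integral_vol,
            })
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_raster(self.dsm, outdir / "dsm.tif")
        write_raster(self.dtm_true, outdir / "dtm_true.tif")
        write_raster(self.nir, outdir / "nir.tif")
        write_raster(self.red, outdir / "red.tif")
        self.truth_frame().to_csv(outdir / "trees.csv", index=False)


def _smooth_noise(shape, gsd, wavelength, amplitude, rng):
    """Band-limited undulation: coarse Gaussian control grid, cubic spline."""
    if amplitude == 0:
        return np.zeros(shape)
    nr, nc = shape
    step_px = max(int(round(wavelength / gsd)), 2)
    cr = np.arange(-step_px, nr + 2 * step_px, step_px)
    cc = np.arange(-step_px, nc + 2 * step_px, step_px)
    control = rng.normal(0.0, amplitude, size=(cr.size, cc.size))
    kx = min(3, cr.size - 1)
    ky = min(3, cc.size - 1)
    spline = RectBivariateSpline(cr, cc, control, kx=kx, ky=ky)
    return spline(np.arange(nr), np.arange(nc))


def _sample_trees(config: SceneConfig, rng) -> list[TreeTruth]:
    lai_lo, lai_hi = config.lai_range
    trees = []
    tid = 0
    for i in range(config.rows):
        for j in range(config.cols):
            tid += 1
            x = config.margin + (j + 0.5) * config.tree_spacing_x
            y = config.margin + (i + 0.5) * config.tree_spacing_y
            d1 = rng.uniform(*config.d1_range)
            d2 = rng.uniform(*config.d2_range)
            ht = rng.uniform(*config.ht_range)
            hb = float(np.clip(rng.normal(config.hb_mean, config.hb_sd),
                               0.3, ht - 1.0))
            lai = rng.uniform(lai_lo, lai_hi)
            # SPAD tracks vigour: greener leaves on leafier trees
            spad = 35.0 + 20.0 * (lai - lai_lo) / (lai_hi - lai_lo) \
                + rng.normal(0.0, 1.0)
            ndvi = 0.30 + 0.40 * lai / lai_hi
            trees.append(TreeTruth(
                tree_id=tid, x=x, y=y, d1=d1, d2=d2, ht=ht, hb=hb,
                lai_true=lai, spad_true=spad, ndvi_true=ndvi,
                hollow_core_fraction=config.hollow_core_fraction))
    return trees


def generate_scene(config: SceneConfig | None = None, seed: int = 0) -> OrchardScene:
    """Render a full scene; identical seed ⇒ bit-identical rasters."""
    config = config or SceneConfig()
    ss = np.random.SeedSequence(seed)
    rng_terrain, rng_trees, rng_ndvi = (
        np.random.default_rng(s) for s in ss.spawn(3))

    width, height = config.extent
    nc = int(round(width / config.gsd))
    nr = int(round(height / config.gsd))
    y_origin = height  # world y decreases with row; scene occupies [0, height]

    def make_grid(values, units):
        return RasterGrid(values=values, x_origin=0.0, y_origin=y_origin,
                          pixel_size_x=config.gsd, pixel_size_y=config.gsd,
                          units=units)

    gx, gy = config.terrain_gradient
    template = make_grid(np.zeros((nr, nc)), "m")
    X, Y = template.cell_centers()
    terrain = (config.terrain_z0 + gx * X + gy * Y
               + _smooth_noise((nr, nc), config.gsd,
                               config.terrain_noise_wavelength,
                               config.terrain_noise_amplitude, rng_terrain))

    trees = _sample_trees(config, rng_trees)

    dsm = terrain.copy()
    crown_label = np.zeros((nr, nc), dtype=int)
    for t in trees:
        a, b, c = t.semi_axes
        # bounding window of the footprint, in pixels
        r0, c1 = template.rowcol(t.x - a, t.y + b)
        r1, c0 = template.rowcol(t.x + a, t.y - b)
        r0, r1 = max(min(r0, r1), 0), min(max(r0, r1) + 1, nr)
        c0, c1 = max(min(c0, c1), 0), min(max(c0, c1) + 1, nc)
        xs = X[r0:r1, c0:c1]
        ys = Y[r0:r1, c0:c1]
        u = ((xs - t.x) / a) ** 2 + ((ys - t.y) / b) ** 2
        inside = u <= 1.0
        z = np.zeros_like(xs)
        z[inside] = t.hb + c + c * np.sqrt(1.0 - u[inside])
        f = config.hollow_core_fraction
        if f > 0:
            r_ell = np.sqrt(u)
            core = inside & (r_ell < f)
            depth = f * (t.ht - t.hb) * (1.0 - r_ell[core] / f)
            z[core] -= depth
        block = dsm[r0:r1, c0:c1]
        block[inside] = terrain[r0:r1, c0:c1][inside] + z[inside]
        crown_label[r0:r1, c0:c1][inside] = t.tree_id

    ndvi = np.full((nr, nc), config.soil_ndvi)
    for t in trees:
        ndvi[crown_label == t.tree_id] = t.ndvi_true
    ndvi = ndvi + rng_ndvi.normal(0.0, config.ndvi_noise_sd, size=(nr, nc))
    ndvi = np.clip(ndvi, -0.95, 0.95)
    nir = 0.3 * (1.0 + ndvi)   # NIR + RED fixed at 0.6
    red = 0.3 * (1.0 - ndvi)

    return OrchardScene(
        config=config,
        dsm=make_grid(dsm, "m"),
        dtm_true=make_grid(terrain, "m"),
        nir=make_grid(nir, "reflectance"),
        red=make_grid(red, "reflectance"),
        trees=trees,
    )


def generate_swp_series(regime: str,
                        doy_grid=None,
                        seed: int = 0,
                        tree_id: str | None = None,
                        noise_sd: float = 0.05) -> SWPSeries:
    """Seasonal stem water potential fixture for one irrigation regime.

    ``regime`` is "irrigated" (SWP held in about [−2.2, −1.4] MPa) or
    "rainfed" (progressive decline toward −4.5 MPa near DOY 267, with a
    mid-season rain recovery and a post-irrigation rebound after DOY
    273).  ``doy_grid`` defaults to weekly sampling over the DOY
    182–273 irrigation window.
    """
    if doy_grid is None:
        doy_grid = np.arange(182, 274, 7)
    doy = np.asarray(doy_grid, dtype=float)
    if doy.size == 0:
        raise ValueError("doy_grid must not be empty")
    if np.any(np.diff(doy) <= 0):
        raise ValueError("doy_grid must be strictly increasing")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = rng.normal(0.0, noise_sd, size=doy.size) if noise_sd > 0 else 0.0

    if regime == "irrigated":
        base = -1.8 + 0.25 * np.sin(2 * np.pi * (doy - 182.0) / 60.0)
        swp = np.clip(base + noise, -2.2, -1.4)
    elif regime == "rainfed":
        # linear decline −1.5 → −4.5 MPa between DOY 182 and 267
        base = -1.5 - 3.0 * np.clip((doy - 182.0) / (267.0 - 182.0), 0, 1)
        # recovery after the DOY-225 rainfall, decaying over ~8 d
        rain = np.where(doy >= 225.0, 0.6 * np.exp(-(doy - 225.0) / 8.0), 0.0)
        # rebound after the single relief irrigation on DOY 273
        relief = np.where(doy > 273.0, 1.2, 0.0)
        swp = np.clip(base + rain + relief + noise, -4.6, -1.2)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return SWPSeries(tree_id=tree_id or regime, doy=doy, swp=swp)
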