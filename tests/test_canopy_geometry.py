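"""Geometric traits: closed forms, raster integration, recovery."""

import numpy as np
import pytest

import canopy3d as c3
from conftest import run_pipeline


def make_segment(mask, grid, label=1):
    area = float(mask.sum() * grid.pixel_area)
    rows, cols = np.nonzero(mask)
    cx, cy = grid.xy(rows.mean(), cols.mean())
    return c3.CrownSegment(label=label, mask=mask, footprint_area=area,
                           centroid_x=float(cx), centroid_y=float(cy),
                           bbox=(rows.min(), cols.min(),
                                 rows.max() + 1, cols.max() + 1))


# -- closed forms ----------------------------------------------------------

@pytest.mark.parametrize("d1,d2,ht,hb,expect", [
    (2.0, 2.0, 2.7, 0.7, 4.0 * np.pi / 3.0),           # unit sphere
    (3.0, 2.0, 3.4, 0.7, 4.0 * np.pi / 3.0 * 1.5 * 1.0 * 1.35),  # 8.4823
])
def test_ellipsoid_volume(d1, d2, ht, hb, expect):
    assert c3.ellipsoid_volume(d1, d2, ht, hb) == pytest.approx(expect)


def test_ellipsoid_volume_degenerate_height_rejected():
    with pytest.raises(ValueError):
        c3.ellipsoid_volume(2.0, 2.0, 0.7, 0.7)


@pytest.mark.parametrize("circ,expect", [
    (2.0 * np.pi, np.pi),
    (0.40, 0.40**2 / (4 * np.pi)),  # 0.012732 m²
])
def test_tcsa(circ, expect):
    assert c3.tcsa(circ) == pytest.approx(expect)


def test_tcsa_rejects_nonpositive():
    with pytest.raises(ValueError):
        c3.tcsa(0.0)


# -- diameter --------------------------------------------------------------

def test_crown_diameter_examples():
    grid = c3.RasterGrid(np.zeros((10, 10)), y_origin=10.0)
    seg = make_segment(np.ones((10, 10), bool), grid)
    seg.footprint_area = np.pi * 1.5**2
    assert c3.crown_diameter(seg) == pytest.approx(3.0)
    seg.footprint_area = 4e-4  # one 2 cm pixel
    assert c3.crown_diameter(seg) == pytest.approx(0.02257, abs=1e-5)
    seg.footprint_area = np.pi * 1.5 * 1.0  # ellipse a=1.5, b=1.0
    assert c3.crown_diameter(seg) == pytest.approx(2.0 * np.sqrt(1.5), abs=1e-3)


# -- volumes ---------------------------------------------------------------

def test_total_volume_uniform_height():
    grid = c3.RasterGrid(np.zeros((10, 10)), y_origin=0.2,
                         pixel_size_x=0.02, pixel_size_y=0.02)
    vals = np.full((10, 10), 2.5)
    ndsm = grid.like(vals)
    seg = make_segment(np.ones((10, 10), bool), grid)
    assert c3.total_volume(ndsm, seg) == pytest.approx(100 * 4e-4 * 2.5)


def test_total_volume_empty_segment_is_zero():
    grid = c3.RasterGrid(np.zeros((5, 5)), y_origin=5.0)
    seg = c3.CrownSegment(label=1, mask=np.zeros((5, 5), bool),
                          footprint_area=0.0, centroid_x=0, centroid_y=0,
                          bbox=(0, 0, 0, 0))
    assert c3.total_volume(grid, seg) == 0.0


def test_below_and_net_volume_rules():
    grid = c3.RasterGrid(np.zeros((10, 10)), y_origin=10.0)
    seg = make_segment(np.ones((10, 10), bool), grid)
    seg.footprint_area = 7.0
    assert c3.below_canopy_volume(seg, 0.7) == pytest.approx(4.9)
    assert c3.below_canopy_volume(seg, 0.0) == 0.0
    with pytest.raises(ValueError):
        c3.below_canopy_volume(seg, -0.1)
    assert c3.net_canopy_volume(10.0, 4.9) == pytest.approx(5.1)
    with pytest.warns(UserWarning, match="clamped"):
        assert c3.net_canopy_volume(3.0, 4.9) == 0.0


def test_missing_tree_in_clearance_table_errors(default_run):
    with pytest.raises(KeyError, match="tree_id"):
        c3.compute_tree_metrics(default_run.scene.dsm, default_run.dtm,
                                default_run.ndsm, default_run.segments,
                                d_table={1: 0.7})  # other labels missing


def solid_ellipsoid_run(gsd, hollow=0.0):
    cfg = c3.SceneConfig(rows=1, cols=1, gsd=gsd, terrain_gradient=(0, 0),
                         terrain_noise_amplitude=0.0, ndvi_noise_sd=0.0,
                         d1_range=(3.0, 3.0), d2_range=(2.4, 2.4),
                         ht_range=(3.4, 3.4), hb_mean=0.7, hb_sd=0.0,
                         hollow_core_fraction=hollow)
    scene = c3.generate_scene(cfg, seed=0)
    ndsm = c3.compute_ndsm(scene.dsm, scene.dtm_true)
    segs = c3.segment_crowns(ndsm, c3.SegmentationParams(
        method="fixed", height_threshold=0.5))
    assert len(segs) == 1
    tree = scene.trees[0]
    total = c3.total_volume(ndsm, segs[0])
    net = c3.net_canopy_volume(
        total, c3.below_canopy_volume(segs[0], tree.hb))
    return tree, net


def test_net_volume_matches_surface_integral_closed_form():
    tree, net = solid_ellipsoid_run(gsd=0.01)
    a, b, c = tree.semi_axes
    assert net == pytest.approx((5.0 / 3.0) * np.pi * a * b * c, rel=0.02)


def test_net_to_ellipsoid_ratio_converges_to_five_fourths():
    errs = []
    for gsd in (0.04, 0.02, 0.01):
        tree, net = solid_ellipsoid_run(gsd)
        errs.append(abs(net / tree.ellipsoid_vol - 1.25))
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 0.005


def test_hollow_core_net_volume_below_ellipsoid_formula():
    """Vase-trained crowns: the raster route sees the empty core that
    the field ellipsoid method cannot, so it reads lower."""
    tree, net = solid_ellipsoid_run(gsd=0.02, hollow=0.5)
    assert net < tree.ellipsoid_vol * 1.25
    assert net == pytest.approx(tree.surface_integral_vol, rel=0.02)


# -- height ----------------------------------------------------------------

def test_height_on_flat_terrain():
    grid = c3.RasterGrid(np.full((40, 40), 100.0), y_origin=40.0)
    dsm_vals = grid.values.copy()
    dsm_vals[18:22, 18:22] = 103.2
    dsm = grid.like(dsm_vals)
    mask = dsm_vals > 100.0
    seg = make_segment(mask, grid)
    assert c3.tree_height(dsm, grid, seg) == pytest.approx(3.2)


def test_height_on_sloped_terrain_first_order():
    # symmetric annulus on a planar slope averages to the terrain at
    # the crown centre, so height ≈ apex − terrain(centre)
    n = 200
    grid = c3.RasterGrid(np.zeros((n, n)), y_origin=n * 0.05,
                         pixel_size_x=0.05, pixel_size_y=0.05)
    X, Y = grid.cell_centers()
    terrain = 100.0 + 0.05 * X
    dtm = grid.like(terrain)
    dsm_vals = terrain.copy()
    cx, cy = 5.0, 5.0
    crown = (X - cx) ** 2 + (Y - cy) ** 2 < 1.5**2
    dsm_vals[crown] = terrain[crown] + 3.0
    dsm = grid.like(dsm_vals)
    seg = make_segment(crown, grid)
    h = c3.tree_height(dsm, dtm, seg, ring_width=1.0)
    apex = dsm_vals[crown].max()
    assert h == pytest.approx(apex - (100.0 + 0.05 * cx), abs=0.02)


def test_empty_annulus_errors():
    grid = c3.RasterGrid(np.full((10, 10), 100.0), y_origin=10.0)
    seg = make_segment(np.ones((10, 10), bool), grid)
    with pytest.raises(ValueError, match="annulus"):
        c3.tree_height(grid, grid, seg)


def test_height_recovery_against_truth(default_run):
    gsd = default_run.scene.config.gsd
    for s, t, _ in default_run.match.pairs:
        m = next(m for m in default_run.metrics if m.tree_id == s.label)
        assert abs(m.height - t.ht) <= 2 * gsd


# -- end-to-end parameter recovery -----------------------------------------

def test_net_volume_recovery_origin_forced(default_run):
    """Estimated vs true net volume over the 15-tree scene: slope within
    [0.95, 1.05] and R² > 0.95 (per-tree clearance mode)."""
    true_v, est_v = [], []
    for s, t, _ in default_run.match.pairs:
        m = next(m for m in default_run.metrics if m.tree_id == s.label)
        true_v.append(t.surface_integral_vol)
        est_v.append(m.net_canopy_volume)
    fit = c3.fit_origin_forced(np.array(true_v), np.array(est_v))
    assert 0.95 <= fit.slope <= 1.05
    assert fit.r2 > 0.95


def test_full_pipeline_volume_accuracy_at_coarse_gsd():
    """Even at 4 cm GSD the full adaptive pipeline stays within a few
    percent of the analytic per-tree volume truth."""
    scene = c3.generate_scene(c3.SceneConfig(gsd=0.04), seed=11)
    run = run_pipeline(scene)
    assert run.match.n_matched == 15
    for s, t, _ in run.match.pairs:
        m = next(m for m in run.metrics if m.tree_id == s.label)
        assert m.net_canopy_volume == pytest.approx(
            t.surface_integral_vol, rel=0.05)
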