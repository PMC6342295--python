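"""Shared fixtures: synthetic scenes and full pipeline runs.

Heavier fixtures are session-scoped so the default 15-tree scene and
its pipeline products are computed once for the whole suite.
"""

from dataclasses import dataclass

import numpy as np
import pytest

import canopy3d as c3


@dataclass
class PipelineRun:
    scene: c3.OrchardScene
    dtm: c3.RasterGrid
    ndsm: c3.RasterGrid
    segments: list
    match: c3.MatchResult
    metrics: list  # TreeMetrics, aligned with segments


def run_pipeline(scene: c3.OrchardScene, d_table_from_truth: bool = True,
                 params: c3.SegmentationParams | None = None) -> PipelineRun:
    """DSM → DTM → nDSM → segments → matched metrics, library route."""
    points = c3.sample_ground_points(scene.dsm)
    dtm = c3.build_dtm(points, scene.dsm)
    ndsm = c3.compute_ndsm(scene.dsm, dtm)
    segments = c3.segment_crowns(ndsm, params)
    match = c3.match_segments_to_truth(segments, scene.trees)
    d_table = None
    if d_table_from_truth:
        d_table = {s.label: t.d for s, t, _ in match.pairs}
    metrics = c3.compute_tree_metrics(scene.dsm, dtm, ndsm, segments,
                                      d_table=d_table)
    return PipelineRun(scene, dtm, ndsm, segments, match, metrics)


@pytest.fixture(scope="session")
def default_scene() -> c3.OrchardScene:
    """The default 3×5-tree orchard at 2 cm GSD (study conditions)."""
    return c3.generate_scene(c3.SceneConfig(), seed=7)


@pytest.fixture(scope="session")
def default_run(default_scene) -> PipelineRun:
    return run_pipeline(default_scene)


@pytest.fixture()
def flat_grid():
    """50×50 m flat DSM at z=100, 0.5 m pixels."""
    return c3.RasterGrid(np.full((100, 100), 100.0),
                         x_origin=0.0, y_origin=50.0,
                         pixel_size_x=0.5, pixel_size_y=0.5)
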