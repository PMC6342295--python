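# canopy3d

Per-tree canopy analytics from UAV photogrammetry rasters of orchards.

Modern orchard management — irrigation scheduling, pruning, biomass and
carbon accounting — needs per-tree estimates of canopy size and vigour.
Measuring crown diameters, heights and volumes by hand with rods and
tapes is slow and assumes an idealized crown shape. `canopy3d`
implements the raster route instead: starting from a digital surface
model (DSM) produced by structure-from-motion photogrammetry of UAV
imagery, plus NIR/RED reflectance bands, it derives a digital terrain
model (DTM), normalizes the surface (nDSM = DSM − DTM), delineates
individual tree crowns by local adaptive thresholding, and integrates
per-pixel volumes into per-tree traits. It is written for
agronomists and remote-sensing practitioners working with grid-planted
orchards (the defaults emulate a mature 5 × 5 m olive planting), and
includes the plant-water-status statistics used to relate canopy growth
to irrigation.

## The method

**Canopy volume.** Each canopy pixel contributes its area times its
height above ground; the per-tree total is the sum over the crown
footprint *S*:

```
V_total = Σ_{p ∈ S} A_p · nDSM_p
V_net   = V_total − A(S) · d
```

where `d` is the canopy-to-ground clearance (orchard mean, default
0.7 m, or a per-tree measurement). The manual field alternative models
the crown as an ellipsoid from crown diameters D1, D2, tree height Ht
and lowest-canopy height Hb:

```
V_ellipsoid = (4π/3) · (D1/2) · (D2/2) · ((Ht − Hb)/2)
```

For a solid half-ellipsoid crown surface the raster route converges to
(5/3)·π·a·b·c = 1.25 × V_ellipsoid — and, unlike the field formula, it
*excludes* the empty core of vase-trained crowns.

**Crown delineation.** Niblack (`v > m_w + k·s_w`) and
Sauvola–Pietikäinen (`v > m_w·(1 + k·(s_w/r − 1))`) local thresholds on
the nDSM separate crowns from ground; 8-connected labeling with a
minimum-area filter yields one segment per tree (no watershed needed
when crowns do not touch).

**Height and diameter.** Height = crown apex elevation − mean terrain
in a surrounding annulus; diameter = equivalent-circle diameter
2·√(area/π) of the projected footprint.

**Vigour and water status.** NDVI = (NIR − RED)/(NIR + RED) per pixel,
averaged per crown; SPAD→chlorophyll via Cab = 0.8271·SPAD − 12.8
(µg cm⁻²). The water stress integral (Myers) accumulates stem water
potential deviation from its seasonal maximum c:
`WSI = |Σ (Ψ̄ᵢ − c)·nᵢ|` (MPa·d), with daily WSI = −WSI/n_days.

A seeded synthetic orchard generator renders DSM/DTM/NIR/RED scenes
with analytic per-tree truth, so the full pipeline is testable without
a field campaign.

## Worked example

```python
import numpy as np
import canopy3d as c3

scene = c3.generate_scene(c3.SceneConfig(), seed=7)   # 15 trees, 2 cm GSD
points = c3.sample_ground_points(scene.dsm)
dtm = c3.build_dtm(points, scene.dsm)
ndsm = c3.compute_ndsm(scene.dsm, dtm)
segments = c3.segment_crowns(ndsm)                    # Sauvola default
match = c3.match_segments_to_truth(segments, scene.trees)
d_table = {s.label: t.d for s, t, _ in match.pairs}   # per-tree clearance
metrics = c3.compute_tree_metrics(scene.dsm, dtm, ndsm, segments,
                                  d_table=d_table)
```

prints (via the obvious summaries):

```
crowns detected: 15 (matched 15/15)
tree 1: height 3.17 m (true 3.17), diameter 2.89 m, net volume 13.60 m3 (true 13.62)
net volume, origin-forced: slope 0.999, R2 1.000, RMSE 0.02 m3
WSI rainfed 143 MPa d vs irrigated 20 MPa d
```

Every synthetic tree is found, heights match the truth to within the
pixel size, and the origin-forced regression of estimated versus true
net volume sits on the 1:1 line. The same pipeline runs from the shell:

```
canopy3d simulate --seed 7 --outdir scene/
canopy3d dtm --dsm scene/dsm.tif --out scene/dtm.tif
canopy3d ndsm --dsm scene/dsm.tif --dtm scene/dtm.tif --out scene/ndsm.tif
canopy3d segment --ndsm scene/ndsm.tif --out scene/crowns.tif
canopy3d metrics --ndsm scene/ndsm.tif --dsm scene/dsm.tif \
    --dtm scene/dtm.tif --crowns scene/crowns.tif --out scene/metrics.csv
```

or end-to-end with `canopy3d run --config run.yaml --seed 7 --outdir out/`.

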