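# skinloc — markerless multi-view 3-D localization of skin features

Computer-assisted navigation in minimally invasive spine surgery needs a
continuously tracked reference on the patient. Today that reference is a set
of adhesive optical markers or a clamped dynamic reference frame — hardware
that can be occluded, dislodged, or simply in the way. `skinloc` implements
the alternative: treat the skin itself as the marker field. Natural skin
features (moles, pigment spots) are detected in simultaneous multi-camera
images, matched across views, and triangulated in the metric frame of the
camera rig, giving a dense cloud of 3-D anchor points with a per-point
quality metric.

The package is aimed at researchers in surgical navigation and biomedical
image analysis who want to study detector choice (MSER vs. SURF), matching
strategy, and 3-D accuracy without access to a physical rig: everything runs
on a built-in, fully ground-truthed synthetic 4-camera simulator, and the
same pipeline accepts real images plus a calibration file.

## Method

For a camera pair (c_i, c_j) the pipeline is:

1. **Intrinsic correction** — undistort each image under the pinhole model
   with radial/tangential polynomial distortion (k1, k2, p1, p2, k3).
2. **CLAHE** — contrast-limited adaptive histogram equalization lifts
   low-contrast skin features above the detector thresholds.
3. **Rectification** — the pair is resampled so epipolar lines become image
   rows. With full calibration a common rotated frame is used; otherwise the
   fundamental matrix F (normalized eight-point, rank-2 enforced, satisfying
   x′ᵀ F x = 0) drives an uncalibrated rectification.
4. **Detection** — MSER (maximally stable extremal regions, via an
   incremental component tree over all 256 thresholds) and/or a fast-Hessian
   ("SURF-style") detector on an integral image. Feature ensembles
   F_c = {f(c,1), …, f(c,n(c))} keep sub-pixel location, scale, and region
   support.
5. **Description & matching** — 64-d upright SURF-style descriptors plus the
   rectified row coordinate; candidates are restricted to a ±2-row scan-line
   band and scored by the sum of squared differences (SSD), with mutual-best
   and ratio filtering.
6. **Triangulation** — each match casts two rays from the camera centers;
   the *midpoint of the common perpendicular* is the 3-D point
   Ψ(c_i|c_j, n) = (x, y, z, e), and the perpendicular segment's length *e*
   (mm) is the **triangulation error**, the central quality metric.
7. **3-D outlier removal** — MSAC fits a plane to the cloud (skin patches
   are locally near-planar); points beyond a millimetre-scale distance are
   discarded. The analyzed area (cm²) is the summed Delaunay triangle area
   of the inliers projected onto the plane.
8. **Statistics & marker benchmark** — per-region mean/std/RMS/min/
   quartiles/max of *e*, feature density, and the discard ratio
   (matched / surviving features); bright circular optical markers are
   detected, triangulated by the same code path, and compared to their known
   3-D coordinates by Euclidean distance.

## Worked example

```python
import skinloc as sl

scene = sl.SceneConfig(seed=7)                      # 4 cameras, 20 blobs, 4 markers
report = sl.run_on_scene(scene, sl.PipelineConfig(seed=7))
for det in ("MSER", "SURF"):
    tot = report["detectors"][det]["total"]
    truth = report["truth"][det]
    print(f"{det}: {tot['n_features']} features over {tot['area_cm2']:.1f} cm^2 "
          f"({tot['features_per_cm2']:.1f}/cm^2), mean e = {tot['mean_mm']*1000:.1f} um, "
          f"discard ratio {tot['discard_ratio']:.2f}, "
          f"recovered {truth['n_recovered']}/{truth['n_blobs']} blobs")

rig = sl.make_rig(scene)
images, gt = sl.render(scene, rig)
res = sl.benchmark_markers(images, rig, gt.marker_centers, pair=(1, 4))
print(f"markers: mean Euclidean distance {res['mean_euclidean_mm']:.4f} mm "
      f"({res['n_matched_to_gt']} markers)")
```

prints

```
MSER: 149 features over 5.9 cm^2 (25.3/cm^2), mean e = 0.6 um, discard ratio 1.00, recovered 20/20 blobs
SURF: 180 features over 13.2 cm^2 (13.7/cm^2), mean e = 27.3 um, discard ratio 1.05, recovered 19/20 blobs
markers: mean Euclidean distance 0.0139 mm (4 markers)
```

On a noiseless rendering both detectors localize essentially every planted
blob; the micrometre-scale mean triangulation error reflects the simulator's
exact geometry. With acquisition jitter of 0.5 px the error grows to
~0.1 mm — sub-millimetre, the regime that matters for navigation.

The same workflow is available from the shell:

```bash
skinloc simulate --out-dir sim --seed 7
skinloc localize --images-dir sim --calibration sim/calibration.json \
        --rois sim/rois.json --out-dir run --detector both --pair 1,4
skinloc benchmark-markers --images-dir sim --calibration sim/calibration.json \
        --markers sim/markers_gt.csv --out markers.csv --pair 1,4
skinloc report run/report.json
```

## Layout

- `skinloc.camera` — pinhole model, undistortion, eight-point F, rectification, rays
- `skinloc.clahe` — contrast-limited adaptive histogram equalization
- `skinloc.mser` / `skinloc.fast_hessian` — detectors and descriptors
- `skinloc.matching` — scan-line SSD matching
- `skinloc.triangulation` — midpoint triangulation and pair selection
- `skinloc.plane` — MSAC plane fit, outlier removal, Delaunay area
- `skinloc.markers` — optical-marker detection and ground-truth comparison
- `skinloc.simulate` — ground-truthed synthetic scenes
- `skinloc.pipeline` / `skinloc.stats` / `skinloc.cli` — orchestration, statistics, CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
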