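# Methods

This note documents the models, algorithms, parameter defaults, and design
choices behind `skinloc`, in the spirit of a methods section: what is
computed, under which assumptions, and what the synthetic experiments do and
do not demonstrate.

## Geometry and units

All world quantities are millimetres in a common rig frame; pixels are
0-based with x = column (rightward), y = row (downward), origin at the
center of the top-left pixel. A camera is a pinhole with intrinsics
(fx, fy, cx, cy), polynomial distortion [k1, k2, p1, p2, k3], and a
world-to-camera rigid transform (R, t); the camera center is C = −Rᵀt.
Image undistortion resamples via the forward distortion map (bilinear);
point undistortion inverts the polynomial by fixed-point iteration (10
iterations, 1e-8 px tolerance). With all coefficients zero both are exact
identities.

The fundamental matrix is estimated by the normalized eight-point algorithm
(Hartley normalization: centroid at origin, mean distance √2), with the
rank-2 constraint enforced by zeroing the smallest singular value. F is
normalized to unit Frobenius norm with the largest-magnitude entry positive,
so estimates are deterministic. The unnormalized variant is exposed for
comparison; on noisy correspondences the normalized version has strictly
smaller median residuals (property-tested).

Rectification uses the calibrated construction when both camera models are
available: a shared rotated frame with the x-axis along the baseline and
averaged intrinsics, which aligns rows exactly for noiseless geometry. When
only correspondences exist, an uncalibrated fallback maps the epipole to
infinity and applies a least-squares matching transform. Both paths are
exposed; the pipeline uses the calibrated one because metric triangulation
needs calibration anyway. A shared vertical re-centering shift keeps the
rectified frames on-grid without breaking row alignment.

## CLAHE

Dialect: per-tile histograms (default 8×8 tiles, 256 bins) are clipped at
`clip_limit` (default 0.01) × tile pixel count; the clipped excess is
redistributed uniformly over all bins in a single pass; each tile's transfer
function is its CDF scaled to [0, 255]; pixels blend bilinearly between the
four surrounding tile mappings. Single-pass redistribution is a deliberate,
deterministic simplification of iterative variants. The implementation is
bit-exact against a straightforward loop reference on small fixtures.
Undistortion precedes CLAHE so that all geometry downstream is metric.

## MSER

Dark-polarity regions are connected components (4-connectivity) of the
level sets {I ≤ t}, t = 0…255; bright polarity runs the identical machinery
on 255 − I. A *region* is a distinct component pixel set; its seed is the
pixel minimizing (intensity, row, col); its variation is
(A(t0+Δ) − A(t0−Δ)) / area, where A(t) is the area of the component
containing the seed at level t (zero below the seed's intensity, clamped at
255). A region is selected when its variation is ≤ `max_variation` (0.25),
no greater than that of its chain neighbours (the next distinct regions
containing the seed below/above), and its area lies in
[`min_area` = 10 px, `max_area` = 1% of the ROI]. Plateaus select every
region on the plateau — co-located nested detections are intentionally kept
(they carry real information about nested pigmentation) and only resolved
at the 3-D outlier stage.

The production implementation is an incremental union-find component tree;
the test suite proves it identical to an exhaustive 256-threshold labelling
oracle on randomized small images. Features are sorted by (y, x, scale)
before indexing so ensembles are deterministic.

## Fast-Hessian detection and descriptors

Box-filter approximations of the scale-normalized Hessian determinant are
evaluated on an integral image over the standard size ladder (9, 15, 21,
27; 15, 27, 39, 51; …), with per-term normalization 1/(9·size) — chosen so
that a Gaussian blob of width σ peaks at the filter of equivalent
σ = 1.2·size/9, matching LoG scale selection (verified against a dense naive
evaluation). Keypoints are 3×3×3 scale-space maxima above
`hessian_threshold` (default 20), refined by a quadratic fit.

Descriptors are 64-d *upright* SURF-style vectors: a 20s×20s window sampled
on a 20×20 grid, 4×4 subregions × (Σdx, Σ|dx|, Σdy, Σ|dy|) of Haar
responses (box side 2s), Gaussian-weighted (σ = 3.3s), unit-normalized.
No orientation is assigned: matching happens on rectified pairs whose rows
are aligned, so rotation invariance would only dilute distinctiveness. The
sampling scale is capped at 6 px so large blobs keep a practical window;
both views are capped identically. Features whose window leaves the image
are dropped from ensemble and descriptor set together; constant-patch
features yield the zero vector and are flagged unmatchable.

## Matching

Candidates must lie within `band` (2 rows) of each other in rectified row
coordinate, and optionally within a disparity range. Cost is the SSD
between unit descriptors (= 2(1 − cosine similarity)); acceptance requires
minimal SSD, mutual best in both directions, SSD ≤ `ssd_max` (1.0), and a
two-sided ratio test (0.8). The ratio's "second best" ignores candidates
within `loc_eps` (1.5 px) of the best candidate's location, so co-located
nested detections do not masquerade as ambiguity. Ties break by smaller row
difference, then smaller index; the full rule is symmetric under swapping
the input sets. Setting `ratio=1, mutual=False` recovers the bare
minimal-SSD scan-line rule.

## Triangulation

Rays are cast from the camera centers through undistorted, de-rectified
pixel coordinates. The closest points on the two rays define the
triangulated feature: their midpoint is (x, y, z) and their separation e
(mm) is the triangulation error. Rays with inter-ray sine below 1e-8 raise
a degeneracy; a closest point behind a camera flags the feature rather than
failing. The midpoint method is the primary path because the error metric
*is* the perpendicular segment length; linear SVD triangulation is provided
only as a cross-check. Pair selection requires the region visible in both
frusta and prefers the widest vergence angle, deterministically.

Before ray casting, matched feature centers are mapped back through the
rectification homography and refined by a blob-adaptive intensity-weighted
centroid in the *original* (undistorted) image: local background from the
window border median, support from the half-contrast connected component,
weights over the component dilated by 3 px (the anti-aliased skirt carries
the sub-pixel information), window grown when the component touches it.
Refining in original geometry avoids the bias the rectification resampling
would imprint on centroids.

## Plane fit, outlier removal, area

MSAC scores a plane hypothesis by Σ min(r², τ²) with τ = 1 mm by default.
When the number of point triples is at most `iterations` (1000), all
triples are enumerated in deterministic order — making results reproducible
and exactly equal to an exhaustive oracle on small instances; otherwise a
seeded generator samples triples. An orientation prior (cone half-angle 60°
around the rig viewing axis, as known from the mount mechanics) discards
implausible hypotheses. The winner is refit by total least squares on its
inliers. The discard ratio is matched features / surviving inliers. The
analyzed area orthogonally projects inliers onto the plane and sums the 2-D
Delaunay triangle areas (scipy.spatial.Delaunay), i.e. the convex hull area
of the projection, reported in cm².

A single plane per region is assumed — adequate for the deliberately flat
skin patches the method targets; curved-surface models are out of scope.

## Optical-marker benchmark

Markers are bright discs. Segmentation thresholds at Otsu's value, with a
second Otsu pass inside the bright class when the first split is
implausibly large (skin images are three-class: dark blobs / skin / bright
markers); a manual threshold overrides. Small components (< 5 px) are
removed. Within each component the chosen detector (MSER or fast-Hessian)
runs on the masked image; the highest-response feature near the component
centroid wins, falling back to the intensity-weighted centroid (large discs
exceed the detector's scale ladder and excite rim responses only).
Matched detections across a camera pair (row clusters on the rectified
geometry, column-ordered within rows — valid for coplanar markers) are
triangulated by the *same* code path as skin features; accuracy is the 3-D
Euclidean distance to the known marker coordinates under greedy
nearest-neighbour assignment (cap 2 mm; equal to exhaustive optimal
assignment for the sub-millimetre perturbations of interest, as tested).

## Synthetic scenes

The simulator emulates the intraoperative acquisition geometry: four
cameras on a 160 mm square, 600 mm above a skin patch, converging on its
center (pairwise vergence > 5°), focal length 6000 px at 640×480 — about
10 px/mm on the skin, comparable to the clinical UHD cameras imaging at
close range (a 2592×1920 preset is included). The patch is a 44×33 mm
plane tilted 3°, carrying 20 dark elliptical blobs (radius 1–2.5 mm,
intensity 60–120 on a 180 background, elongation ≤ 1.8, out-of-plane jitter
σ = 0.2 mm so the MSAC stage has real work) and 4 bright corner markers
(radius 3 mm, intensity 250). Rendering rasterizes each analytic ellipse
through its exact plane-to-image homography with 8× supersampled coverage;
projected centroids are faithful to ~10⁻³ px, which is what makes the
micrometre-scale noiseless triangulation errors meaningful.

Noise model: `noise_sigma` (px) displaces each camera's rendered content by
an independent Gaussian sub-pixel offset — acquisition jitter that the
calibration does not know about, the dominant error source in a rigid rig.
Ground truth records the *exact* geometry, so jitter shows up as
localization error; the pipeline error grows monotonically with it
(≈0.001 / 0.05 / 0.10 / 0.17 mm at 0 / 0.25 / 0.5 / 1 px on the compact
preset) and stays sub-millimetre at 0.5 px. Additive grey-level noise
(`intensity_noise`) and a linear illumination gradient are separate fields.
All randomness is seeded; identical seeds give bit-identical images.

What the simulator does **not** emulate: skin texture and specular
reflections, hair, blood, breathing deformation, photometric differences
between cameras, and realistic lens flare. Passing the synthetic suite
therefore demonstrates the geometric and algorithmic correctness of the
pipeline, not clinical performance; on real images the feature density and
discard ratios will differ substantially.

## Statistics and reporting

Per region: mean, sample standard deviation (ddof = 1), RMS = √mean(e²),
min, quartiles (linear interpolation between order statistics, the common
"type 7" convention), max of the inlier triangulation errors, the analyzed
area (cm²), features/cm², and the discard ratio. The pooled "TOT" row is
recomputed on the concatenated error vector, not averaged from per-region
rows. Reports are byte-identical across runs with the same configuration
and seed.

## Problem sizes

Tests and the acceptance script run on the 640×480 default scene (one
full-frame region) and the 320×240 compact preset for multi-seed sweeps
(5–10 seeds per noise level); oracle-equivalence suites use ≤ 24×24 images
for MSER and 20-vs-20 descriptor sets for matching. These sizes were chosen
so the full validation cycle completes in minutes on a single core while
still exercising every stage at realistic feature counts.

## Known limitations

- Single-plane outlier model; strongly curved anatomy would need piecewise
  or quadric fits.
- Upright descriptors assume rectified matching; the detectors themselves
  are rotation-covariant but the descriptor is not rotation-invariant.
- The fast-Hessian ladder tops out at filter size 99; very large blobs
  (> ~15 px radius equivalent σ) are localized via MSER or the centroid
  fallback instead.
- Marker appearance is modelled as a plain bright disc; printed marker
  patterns would require an ID-decoding stage that is out of scope.
- Per-pair triangulation only; features seen by three or more cameras are
  not fused into a single N-view estimate, and results from different
  camera pairs are reported separately.
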