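# Methods

`herdrecon` reconstructs a watertight-ish surface mesh of a livestock-scale
body from a hand-held RGB-D scan (a sequence of registered gray + depth
images with known pinhole intrinsics). The design is the classical
fragment-based offline pipeline: short sub-sequences are tracked densely and
fused into *fragments*, fragments are registered pairwise (with loop-closure
candidates), a robust pose graph distributes the corrections, and all frames
are fused into one truncated-signed-distance volume whose zero isosurface is
the result. An optional final pass jointly refines the fragment poses and a
low-dimensional depth-calibration model.

This note records the models, the parameters that matter, the numerical
choices, and what the synthetic test bed does and does not establish.

## Stereo depth

Rectified-stereo depth follows `depth = B * fx / disparity` on valid pixels
(disparity > 0); disparity 0 is the invalid sentinel everywhere. The default
baseline `B` is 50 mm, a common stock stereo-camera geometry. The built-in
matcher is a semi-global scheme: census transform (5x5) plus a truncated
absolute intensity difference as the per-pixel cost, scanline aggregation
over 8 directions with the standard P1/P2 smoothness recurrence (defaults
8/96), winner-take-all with parabolic subpixel refinement, and a 1 px
left-right consistency check whose failures are invalidated to 0. The census
term is robust to gain/offset changes (overexposure); the intensity term
keeps low-texture regions discriminative. The pipeline accepts externally
produced disparity or depth images unchanged, so any matcher can be
substituted.

## Dense RGB-D odometry

Frame-to-frame motion minimizes a joint objective over the valid pixels of
the source frame,

    E(T) = (1 - sigma) * E_I(T) + sigma * E_D(T),

where `E_I` sums squared intensity differences between a pixel and its warp
into the target frame (unproject with the source depth, transform by `T`,
project), and `E_D` sums squared differences between the target depth at the
warped pixel and the z of the transformed point. `sigma = 0.5` by default;
either extreme gives a pure photometric or pure geometric tracker.
Photometric residuals carry Huber weights (scale 0.03 intensity units) so
saturated patches do not dominate; geometric residuals are gated at 70 mm.

Minimization is damped Gauss-Newton on a left-multiplied se(3) increment,
coarse to fine over a 3-level image pyramid (2x box downsampling,
valid-aware for depth). Two numerical points proved load-bearing:

* **Silhouette exclusion.** Warped depth samples must lie inside a
  1-px-eroded valid-depth mask. Finite-difference depth gradients straddling
  the silhouette are meaningless and, if admitted, dominate the normal
  equations and push the solver into spurious minima.
* **Fixed-domain step acceptance.** A step is accepted only if it lowers the
  objective evaluated on the *intersection* of the old and new valid-pixel
  sets (and keeps at least half the overlap). Comparing re-gated means lets
  a step "improve" the objective by shrinking the overlap instead of
  aligning it.

Measured accuracy on noise-free synthetic scans at 320x240 (2-degree / 2 cm
motions, oblique viewpoint): median 0.08 deg and ~2.3 mm, with a floor set
by bilinear-interpolation bias of the renderer, not by the optimizer.
Chained over 10 orbit frames the same-sign bias accumulates to roughly
0.3 deg / 8 mm; the pipeline removes this drift downstream via fragment
registration and the pose graph. On-axis views of the elongated body make
yaw and lateral translation near-degenerate; accuracy figures are quoted at
oblique viewpoints where the motion is observable.

For non-adjacent frames a wide-baseline initializer matches FAST-corner
patches, lifts them to 3D through the depth images, and fits a rigid
transform inside RANSAC. Depth being available makes an essential-matrix
(5-point) solver unnecessary.

## Global registration

Fragment clouds are voxel-downsampled (25 mm) and described by 33-bin FPFH
histograms (three Darboux angles, 11 bins each, neighbor-weighted
aggregation, per-block normalization). The support radius is 4x the voxel —
at 2.5x, cross-fragment mutual matches were an order of magnitude scarcer
and mostly wrong. Correspondences are mutual nearest neighbors in feature
space pruned by the random-3-tuple length-ratio test (ratios within
[0.9, 1.11]).

The robust objective `E(T) = sum rho(p - T q)` uses the scaled Geman-McClure
penalty `rho(r) = mu |r|^2 / (mu + |r|^2)` with graduated non-convexity: each
outer iteration computes closed-form line-process weights
`l = (mu / (mu + |r|^2))^2` and re-fits `T` by the exact weighted Kabsch
solution (which minimizes the weighted objective exactly, so the joint
line-process objective is non-increasing without damping machinery); `mu`
anneals from `(diameter/2)^2` by a factor 1.4 every 4 of 64 iterations down
to (5 mm)^2. In the no-downweighting limit (one iteration at enormous `mu`)
the result equals the closed-form least-squares fit, which the tests check
against an independent oracle. A correspondence-RANSAC solver (3-point
hypotheses, inlier counting, final inlier refit, fully seeded) is provided
as the comparison baseline.

## Local refinement

Three ICP variants share the correspondence machinery (nearest target
neighbor within a distance gate):

* point-to-point — exact closed-form rigid refit per iteration;
* point-to-plane — damped Gauss-Newton on
  `E(T) = sum ((p - T q) . n_p)^2`;
* colored — `E = (1 - delta) E_C + delta E_G` with `delta = 0.968`, where
  `E_C` evaluates a precomputed linear intensity model on the target point's
  tangent plane (value plus in-plane least-squares gradient) at the
  orthogonal projection of `T q` and compares it with the source intensity.

With `delta = 1` the photometric rows vanish identically and the update
coincides with point-to-plane ICP iterate for iterate (verified to 1e-12).
Colored ICP runs a coarse-to-fine multi-scale schedule, by default voxels
(20, 10, 5) mm with (50, 30, 14) iterations and correspondence distance 2x
the voxel. Steps that would increase the objective on the current
correspondence set are rejected with 10x damping escalation, so the
per-iteration objective is non-increasing. The tangent-plane projection of
the color model is orthogonal (not along the viewing ray) — the standard
reading, and the one that keeps the gradient strictly in-plane.

On a textured plane shifted 5 mm in-plane, point-to-plane leaves
essentially the whole shift (sliding is unobservable to it) while the
colored variant recovers it to ~0.01 mm; this degenerate-geometry
separation, and the faster convergence of point-to-plane over
point-to-point (median 2 vs 5 iterations to 0.1 mm RMSE on perturbed
surface patches), are both asserted in the suite.

## Pipeline, pose graph

Scans are split into consecutive `k = 100`-frame segments (a trailing
remainder shorter than k/2 merges backward). Within a fragment, odometry is
chained with identity initialization (wide-baseline initialization is a
fallback on failure) and the frames are fused by a local TSDF (15 mm voxels,
every 2nd frame) whose extracted point cloud (with TSDF-gradient normals and
fused intensity) represents the fragment. Adjacent fragment pairs are
initialized by the aggregated odometry; *all* non-adjacent pairs are tried
as loop-closure candidates (fragment counts are tiny, so all-pairs is
affordable): FPFH + FGR for the coarse alignment, then colored-ICP
refinement; an edge is valid if the refined fitness reaches 0.3. Edge
information matrices are the point-to-plane Gauss-Newton `J^T J` over the
inlier correspondences at convergence.

The pose graph minimizes

    sum_e w_e ||log(T_e^-1 X_i^-1 X_j)||^2_Info + mu sum_lc (sqrt(w_e) - 1)^2

with node 0 fixed as the gauge and odometry edges pinned at `w = 1`.
Loop-closure weights use the closed-form update `w = (mu/(mu + r^2))^2`;
`mu` anneals from above the worst initial inconsistency down to 10x the
median odometry-edge residual cost (recomputed each outer iteration), so
consistent closures converge to `w ~ 1` while gross outliers switch off
(weights < 1e-4 in the controlled-corruption tests). Pose updates are damped
Gauss-Newton with forward-difference Jacobians — graphs have at most a dozen
nodes, so exactness beats cleverness. On a simulated 5-fragment drift chain
with one exact closure the trajectory error drops by ~65-75%.

The per-pipeline JSON report contains only deterministic quantities (wall
times go to a separate file), so a rerun under the same seeds reproduces it
bit for bit — asserted on a 200-frame synthetic scan.

## TSDF fusion

A dense axis-aligned grid (sized from the posed frames' unprojected bounding
box plus margin) stores per voxel a truncated signed distance in [-1, 1],
an integration weight, and an intensity accumulator. Defaults: 8 mm voxels
for final animal-scale fusion, truncation 4 voxels, weight cap 100 (late
frames stay influential under drift). Per frame, every voxel center projects
into the camera; the depth is sampled *bilinearly* with all four support
pixels required valid and 1-px interior (nearest-pixel sampling at coarse
image resolutions biases oblique surfaces by many mm; silhouette pixels are
excluded for the same reason as in odometry). The projective along-ray
signed distance is scaled by the incidence cosine (per-pixel normals from
the unprojected depth map) to approximate the perpendicular distance — this
removes the outward bias at grazing views — while the behind-surface band
test uses the *unscaled* along-ray distance so far-behind voxels cannot
creep into the band via a small cosine. Observations at incidence cosine
below 0.15 are skipped; the integration weight is the cosine itself.

Extraction runs marching cubes on the field with unobserved voxels filled
at +1 (never on the isolevel), then removes every triangle touching a cell
whose 8 corners were not all observed. The fill-plus-cut combination is what
eliminates phantom sheets both at occlusion boundaries and at the carving
frontier ~1 truncation inside the body. Vertex intensity is trilinear from
the accumulator; point-cloud normals come from the TSDF gradient. On a
noise-free synthetic sphere orbit fused at known poses the 95th-percentile
vertex-to-surface error is ~2 mm at 8 mm voxels (sub-voxel), and integration
is order-independent to float associativity.

## Depth-calibration refinement (simplified SLAC)

Residual inter-fragment misalignment that rigid poses cannot absorb is
modeled as a 2-coefficient multiplicative radial depth correction,

    d_corrected = d * (1 + a1 r^2 + a2 r^4),   r = image radius / corner radius,

the dominant distortion mode of stereo depth cameras. This is a deliberate,
documented simplification of control-grid SLAC (the full method embeds a
deformation lattice); it plays the same pipeline role — drift and outlier
reduction — while being recoverable and testable at desk scale. The sanity
bound keeps the correction factor within [0.9, 1.1].

`slac_optimize` alternates, on mutual-nearest inter-fragment correspondences
(recomputed each outer iteration, gated at 15 mm): (a) damped Gauss-Newton
on the fragment poses with analytic point-to-plane Jacobians, and (b) exact
linear least squares on (a1, a2) — both residual forms are linear in their
block, so each half-step is non-increasing at fixed correspondences. Samples
are taken every 4th frame at pixel stride 2 (up to 8000 points per
fragment); fragment-frame normals are estimated once (k = 24) and rotated.
On clean data the identity model and poses are recovered to ±0.002 and
0.03 deg / 0.8 mm; with an injected a1 = 0.02 distortion the fitted
correction magnitude is ~0.0178 against a polynomial-inverse target of
0.0196-0.0200 (the r^2/r^4 columns are nearly collinear over the observed
radius range, which is why a1 alone is quoted by magnitude), and applying
the fitted correction cuts the fused 95th-percentile surface error by ~90%.

## Synthetic scene generator

The generator emulates a walk-around scan of a standing cow-sized animal so
every stage is testable without recordings. The body is an implicit union
(superellipsoid trunk, four leg capsules, neck capsule, head ellipsoid)
polygonized by marching cubes — watertight and manifold by construction —
lightly Taubin-smoothed and rescaled so the longest bounding-box axis equals
the requested size (default 2.2 m). Per-vertex albedo is multi-octave
band-limited noise plus high-contrast dark/light patches (cow-like markings:
the photometric signal colored ICP and the SGM matcher rely on).

The camera orbit is a circular arc (default 2.5 m radius, 270 degrees, 500
frames) with the optical axis through the body center; consecutive-pose
rotation stays well under 3 degrees. Rendering is a perspective-correct
z-buffer rasterizer (numba-jitted) with Gouraud-shaded Lambertian intensity
under a **fixed directional world light** plus ambient — static illumination
is both the physically right model of a statically lit barn and the regime
in which Lambertian shading is view-independent, i.e. in which the
photometric-constancy assumption of dense alignment actually holds. (A
camera-attached light was tried first and produced a systematic ~0.2 deg
per-pair odometry bias along orbits; the fix is a fidelity correction of the
generator, and the bias mechanism is worth knowing about for real headlamp-
lit recordings.) Depth is exact at pixel centers (unprojected points lie on
the mesh to ~1e-15 m).

Noise, all seeded: Gaussian depth noise with sigma(d) = sigma0 (d/1m)^2
(default sigma0 = 2 mm — stereo-like quadratic growth), uniform dropout
(2%), and saturated elliptical "overexposure" patches (~0.5 per frame).
Stereo pairs displace the right camera by the baseline along +x and return
the exact ground-truth disparity of the left view.

**What passing tests do and do not show.** The generator provides exact
geometry, exact Lambertian photometry, rigid scenes, and noise of known
form. Passing therefore demonstrates correctness of the estimators and
their documented convergence/robustness envelopes — not performance under
fur, specularity, motion blur, articulated movement (a swishing tail),
rolling-shutter effects, or real stereo-matcher artifacts. Where real data
would stress the system hardest (photometric violations, depth bias), the
suite injects controlled counterparts (overexposure patches, radial depth
distortion) rather than claiming realism.

## Problem sizes and budgets

Tests and the acceptance script run everything at deliberately modest
scales chosen as honest miniatures: images 160x120 to 320x240, 60-200 frame
sequences, fragments of 15-100 frames, fusion voxels 8-20 mm, animal size
2.2 m. Generator *defaults* keep the full-scan conditions (500 frames,
k = 100, 50 mm baseline, 2.5 m orbit). The end-to-end pipeline at these
sizes reaches ~14 mm trajectory RMSE and ~7 mm 95th-percentile surface
error against ground truth, limited mainly by odometry warp-interpolation
bias at 160x120; both improve with resolution.

## Known limitations

* Purely rigid scenes; animal motion is out of scope (the pipeline's
  drift-correction stages absorb small quasi-static deformation only).
* The depth-calibration model is radial-only; per-pixel or lattice
  distortion fields are not represented.
* The SGM baseline is a reference implementation (dense scanline DP at
  Python/numpy speed), not a production matcher.
* On-axis views of elongated bodies leave a near-degenerate yaw/translation
  direction in dense odometry; orbit-style scanning (always oblique) avoids
  it, and the pose graph absorbs the residual drift.
* `a1`/`a2` of the distortion model are individually ill-conditioned when
  the subject occupies only the image center; the fitted *function* over the
  observed radius range is what is well determined.
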