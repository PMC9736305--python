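# herdrecon

3D surface reconstruction of livestock from hand-held RGB-D scans.

Body measurements of dairy cattle — stature, rump width, udder conformation
— correlate with fertility, milk yield and longevity, and a metric 3D point
cloud of the animal lets them be computed automatically instead of by tape
and eye. Scanning a standing animal is awkward: one walks a stereo depth
camera around the cow, the overlap between successive views is limited, the
animal is smooth and weakly textured, and small frame-to-frame tracking
errors accumulate into visible drift and outlier sheets in the fused model.
`herdrecon` implements the full offline pipeline that turns such a scan
into a clean mesh, plus a ground-truthed synthetic scan generator so every
stage is testable without recordings.

The pipeline, in the field's standard notation:

1. **Stereo depth** — `depth = B·fx / disparity` on valid pixels
   (disparity > 0); a census + intensity semi-global matcher is included as
   the classical baseline, and externally produced depth plugs in directly.
2. **Dense RGB-D odometry** — frame-to-frame motion `T` minimizes
   `E(T) = (1−σ)·E_I(T) + σ·E_D(T)`, the joint photometric/geometric
   objective over warped pixels `x' = g(T·h(x, D(x)))`, by coarse-to-fine
   damped Gauss–Newton (σ = 0.5).
3. **Fragments** — each k-frame segment (k = 100) is fused by a local TSDF
   into a partial surface cloud.
4. **Global registration** — FPFH correspondences optimized under
   `E(T) = Σ_{(p,q)∈K} ρ(p − T·q)` with a scaled Geman–McClure penalty and
   graduated non-convexity (FGR); correspondence RANSAC as baseline.
5. **Refinement** — point-to-plane ICP `E(T) = Σ ((p − T·q)·n_p)²` and
   colored ICP `E(T) = (1−δ)·E_C + δ·E_G` (δ = 0.968), multi-scale; with
   δ = 1 colored ICP reduces exactly to point-to-plane.
6. **Pose graph** — fragment poses minimize
   `Σ_e w_e‖log(T_e⁻¹ X_i⁻¹ X_j)‖²_Λ + μ Σ_lc (√w_e − 1)²`, a line process
   that switches off inconsistent loop closures.
7. **TSDF fusion** — weighted running-average integration of all posed
   frames, marching-cubes extraction.
8. **SLAC-style refinement** — joint re-optimization of fragment poses and
   a radial depth-correction model
   `d' = d·(1 + a₁r² + a₂r⁴)` that absorbs the dominant stereo-depth
   distortion mode.

Conventions: pixel coordinates are 0-based `(u, v) = (column, row)`; depth
is metric with 0 as the invalid sentinel (16-bit PNG at 1000 counts/m on
disk); trajectories are TUM-format text; clouds and meshes are PLY.

## Worked example

Generate a noise-free 60-frame synthetic scan of a procedural 2.2 m
animal, reconstruct it, and score the result against the generator's
ground truth:

```
herdrecon synth demo --frames 60 --width 160 --height 120 --seed 4 --no-noise
herdrecon run demo --out demo_out --k 30 --seed 0 --no-slac
herdrecon evaluate demo_out/trajectory.tum demo/groundtruth.tum \
    --mesh demo_out/mesh.ply --truth-mesh demo/groundtruth_mesh.ply
```

The `run` report shows the scan splitting into two 30-frame fragments whose
single adjacent pair registers with fitness 0.41 and inlier RMSE 6.7 mm,
and a fused mesh of ~48k vertices at 12 mm voxels. The evaluation prints

```
{
  "ate_m": 0.005286676089580075,
  "surface_error_m": {
    "p50": 0.001874476696803672,
    "p95": 0.0046161741836805124,
    "p100": 0.026254509620916515
  }
}
```

i.e. the estimated camera trajectory is within 5.3 mm RMSE of ground truth
(after removing the unobservable global gauge), and 95% of reconstructed
mesh vertices lie within 4.6 mm of the true surface — about a third of the
fusion voxel size, at a deliberately small 160×120 image resolution.

`docs/methods.md` describes the models, parameter defaults, numerical
choices, and what the synthetic test bed does and does not establish.

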