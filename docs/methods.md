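# Methods

This note documents the models, conventions, numerical choices and known
limitations of `fluorokin`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Conventions

* Lengths in mm, angles in degrees at API boundaries; radians internally.
* Pixels are 0-based with centres on integer coordinates; `u` rightward,
  `v` downward. An image array is indexed `[v, u]`.
* `Pose6DOF` = (x, y, z, α, β, γ): translations plus **intrinsic x→y→z**
  rotations about the body's own axes. This parameterizes the optimizer's
  design variables and is deliberately decoupled from clinical reporting;
  joint angles always use the intrinsic **z–x–y Cardan** sequence (flexion
  about the femoral z, adduction about the floating x, internal rotation
  about the tibial y). Gimbal lock (middle angle ±90°) raises an error
  naming the degenerate axis.
* An X-ray unit is an ideal point-source perspective camera: source
  position, detector origin (3D position of pixel (0,0)), orthonormal
  in-plane axes, pixel spacing, resolution. Calibration is an input (or
  synthetic ground truth), never estimated from images.

## Pseudo-volumes and DRRs

A watertight surface is voxelized by slice parity: per transverse (y, z)
grid line, every ray/triangle crossing toggles the interior state of all
voxel centres beyond it (a vectorized flip-and-cumsum), so centres with odd
crossing parity are interior. Centres in the half-open interval
[entry, exit) count as interior — a centre exactly on the entry surface counts as bone, on the
exit surface as air. This tie-break is deterministic and keeps the line
integral of the trilinear field unbiased (a strictly-inside rule would
shorten every chord by one voxel). Rays that graze vertices or edges are
avoided by a fixed sub-micrometre offset of the grid; odd crossing counts
that survive are dropped for that line. Interior = 700 HU (homogeneous
cortical bone surrogate), exterior = −1000 HU (air); the final
reconstruction volume uses the clinical 0.5 mm slice pitch, the coarse
search 1.0 mm.

DRRs integrate `(value − air)` along source→pixel rays with trilinear
sampling at half the smallest voxel spacing (per-ray AABB clipping; missed
rays are 0). A numba kernel accelerates the sampling; the numpy path is the
reference and the test suite checks the renderer against an independent
fine-step (spacing/8) ray-marching oracle. 8-bit output uses per-frame
affine min–max normalization — gradient correlation is invariant to
positive affine intensity maps, so this cannot bias registration.

## Similarity and search

Gradient correlation applies the standard 3×3 Sobel pair; window border
pixels are excluded so every gradient sample is fully supported. Both NCC
terms are mean-subtracted and normalized by a single square root of the
product of sums-of-squares, so identical windows score exactly 2. The
similarity window is the projected bounding box of the posed volume's AABB,
dilated 10 px by default; the tracker narrows this to 4 px because at
128 px resolution (≈2 mm pixels) a 20 mm margin would pull the other
bone's edges into the window and measurably bias the optimum.

The optimizer is a seeded real-coded genetic algorithm: tournament
selection (size 3), BLX-α blend crossover (rate 0.9, α = 0.5), per-gene
Gaussian mutation (rate 0.1, σ = 5 % of the bound width), elitism 2. The
initial pose (or the zero shape-coefficient vector) is always injected into
the first population, so the returned best is never worse than the
starting point. An optional Nelder–Mead polish (bounded, ≤80 iterations)
refines the GA optimum; tracking enables it by default. Identical seeds
give bit-identical trajectories.

## Two-phase shape reconstruction

Phase 1 is coarse-to-fine: a pose-only GA with the mean shape first (its
single voxelization is cached, so these evaluations cost only the DRRs),
then a joint 16-parameter GA (6-DOF pose + coefficients of modes 1–10,
bounded at ±3 standard deviations, i.e. ±3√λ_k) whose initial population is
anchored on the pre-searched pose, then a bounded Powell refinement
(≤400 evaluations). Phase 2 freezes pose and the first 10 coefficients and
searches modes 11–20 the same way (GA seeded with zeros + Powell ≤200), so
its objective can only improve on phase 1.
The objective sums −f_GC over every image of every pair; per-pair frames
are entered through the marker-derived rigid transforms (markers are
triangulated by radio-stereometric analysis — closed-form midpoint of the
common perpendicular — then the per-pair clouds co-registered by a Kabsch
fit). Candidate voxelizations are cached on the rounded coefficient vector,
so pose-only moves are cheap.

## AIMT tracking

Stage 1 — the 2D template tracker is an **annealed** particle filter: 300
particles over (Δu, Δv, Δθ), random walk σ = (2 px, 2 px, 2°) shrinking by
half each of 4 passes, likelihood ∝ exp(NCC/τ) with τ = 0.005, systematic
resampling. A single non-annealed pass (the first design tried) left the
weighted mean badly shrunk toward the prior — it could not resolve a 2°
in-plane rotation — so the annealed variant is the default. Per-view
increments map to 3D through the geometric magnification at the model
centroid and compose as rotation vectors about each view's principal axis;
the prediction applies half an increment because registration alternates
planes every half frame interval.

Stage 2 — the pseudo-synchronous partner image is the motion-compensated
midpoint of the partner plane's neighbouring frames: dense displacement
fields both ways from iterative Lucas–Kanade optical flow
(`skimage.registration.optical_flow_ilk`, radius 7), half-warps of both
frames blended. This stands in for block-matching interpolators with the
same role; frames whose plain correlation falls below 0.15 are blended
arithmetically and flagged degenerate.

Stage 3 — bi-plane registration around the predicted pose within ±3 mm/±3°
bounds (widened ×2 after a lost track). The first frame's pose is an
explicit input, mirroring static subject calibration.

## Evaluation metrics

Point-to-surface distance is the exact point-to-triangle minimum
(KD-tree over triangle centroids with a provable pruning radius, then exact
region classification); a vertex-only approximation exists behind a flag
but is off by default. Surface RMSe first removes the rigid part by ICP
(PCA-initialized over all four proper axis-sign combinations, trimmed 95 %,
closest-vertex matching with lowest-index tie-break), then takes the RMS of
the evaluated model's vertex distances to the reference surface —
one-directional by definition. mTRE transforms the evaluated mesh by
`truth⁻¹ ∘ registered` and averages the distance to the reference surface
in its own frame; mmTRE/pmTRE are the cycle mean/peak, success is
mTRE < 1.5 mm (configurable constant).

## The synthetic world

The simulator is a stated world, not a tuning dial:

* **Bones** are procedural analogs of the distal femur (two condyle-like
  lobes plus an anterior trochlea-like bump) and proximal tibia (two
  plateau lobes, tuberosity bump) built on a watertight icosphere; their
  asymmetry suffices to define an anatomical frame and break silhouette
  ambiguities. They are not anatomical — every claim the tests make is
  parameter recovery, not anatomy.
* **Shape population**: 20 orthonormal smooth displacement modes (sums of
  random Gaussian bumps) explicitly orthogonalized against the 6-dim
  linearized rigid subspace, so they are pure shape. Twenty informative
  modes match the reconstruction's 10 + 10 phase structure — with fewer,
  the trailing principal components are rank-deficient noise directions and
  phase 2 has nothing real to recover. Mode SDs are stated as per-vertex
  RMS displacement: 1.5 mm × 0.8^k, giving subject-vs-mean surface RMS of
  ≈2–3 mm — the variability a bone SSM must absorb. The training database
  has 60 shapes; held-out subjects use weights never seen in training.
* **Geometry**: two orthogonal units, source–detector 1000 mm,
  source–isocenter 820 mm (chosen so both bones stay inside a 128 px
  detector over the full motion for all tested seeds), detector width
  256 mm. Frames are 512×512 by default (the clinical resolution), 128×128
  in desk-scale runs.
* **Motion**: sinusoidal 0–60° flexion over a 2 s cycle about the lab z
  axis through the joint centre (femur static), or a constant-velocity
  drift mode used to isolate the benefit of pseudo-synchronization.
* **Imaging**: per-frame rendering at the true timestamp (real asynchrony,
  30 fps/plane, 1/60 s offset), additive Gaussian intensity noise σ = 2
  gray levels, 8-bit quantization. Lead-marker observations are projected
  exactly and optionally jittered in pixels.

What a green test does **not** establish: robustness to soft-tissue
clutter, scatter, beam hardening, detector distortion, non-rigid
calibration error, or anatomically realistic shape statistics. The
marker-jitter tolerance (pair rotation < 0.5° at 0.5 px jitter) holds at
the clinical 512 px resolution; at 128 px the same pixel jitter is
physically four times larger.

## Effect sizes at desk scale

At 128 px (≈1.6 mm object-plane pixels) the reconstruction error is
search-limited: the 20-mode subspace can express a held-out subject almost
exactly, yet the two-phase optimizer settles around 0.5–1.5 mm RMSe
depending on seed. The clinical orderings (phase 2 ≤ phase 1; two pairs ≤
one pair, both in median over 10 seeds) reproduce, but the pair ordering's
margin is far smaller than the per-seed scatter — it should be read as "two
pairs are not worse", not as a measured effect size. The benefit of
motion-compensated pseudo-synchronization, by contrast, is large and
decisive at this scale (an order of magnitude in pose error at the 60 mm/s
drift the flexion cycle peaks at).

## Known limitations

* Internal/external rotation of near-axisymmetric analogs is the weakest
  observed direction; surface-based metrics (mTRE) absorb this, joint-angle
  errors about the long axis can be larger.
* The ACS construction (inertia axes + articular-region origin) is a
  deterministic stand-in for landmark-based anatomical definitions; frames
  are therefore transferred from a reference model by ICP rather than
  recomputed per shape.
* GPA is translation+rotation only by default (bone size is a genuine
  shape feature); scale removal is available as an option.
* Tracking is strictly causal except for the one-frame lookahead the
  midpoint interpolation needs; the last frame of a sequence is not
  registered.
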