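# fluorokin

Measuring 3D knee kinematics with clinical **interleaved bi-plane
fluoroscopy** — where the two X-ray units fire alternately, so no two frames
are ever simultaneous — normally requires a CT scan to build the
subject-specific bone model. `fluorokin` implements the full alternative
pipeline:

1. **Statistical shape model (SSM) reconstruction** of a subject-specific
   bone surface from a handful of static radiograph pairs: a two-phase
   genetic-algorithm search over the 6-DOF pose plus the first 10, then the
   11th–20th principal-component coefficients, scored by how well pseudo-DRRs
   of the candidate shape match the radiographs.
2. **Alternating interpolation-based model tracking (AIMT)** of the bone
   through the interleaved sequence: per frame, a particle-filter 2D template
   tracker predicts the pose, motion-compensated frame interpolation
   synthesizes the other plane's image at the same instant, and a bi-plane
   3D/2D registration refines the 6-DOF pose by maximizing **gradient
   correlation** (the sum of normalized cross-correlations of the horizontal
   and vertical Sobel-gradient images) between DRRs and the pseudo-synchronous
   pair.
3. **Joint kinematics** as the tibial anatomical frame expressed in the
   femoral one, with rotations decomposed by the intrinsic z–x–y Cardan
   sequence (flexion/extension, adduction/abduction, internal/external).
4. **Accuracy metrics**: point-to-surface distance e(p, S), surface RMSe,
   per-frame mean target registration error (mTRE) with its cycle mean
   (mmTRE) and peak (pmTRE), the 1.5 mm registration-success criterion, and
   per-component MAD/PAD between kinematic series.
5. A fully seeded **synthetic fluoroscopy simulator** — procedural bone-shape
   populations with known variation modes, calibrated orthogonal bi-plane
   geometry, lead-marker observations, static multi-view acquisitions and
   interleaved dynamic sequences — so every stage is testable against exact
   ground truth with no external data.

The intended users are researchers in skeletal biomechanics and medical image
analysis who want a reference implementation of DRR-based bi-plane
registration with asynchronous frames, or a controlled test bed for their own
trackers.

## Core quantities

The registration cost over N views sharing one pose
(x, y, z, α, β, γ) is

    cost = Σ_views − f_GC(I_DRR(pose), I_fluoro),
    f_GC = NCC(dI_f/di, dI_D/di) + NCC(dI_f/dj, dI_D/dj)  ∈ [−2, 2],

minimized by a seeded elitist genetic algorithm. Shape candidates are
synthesized as `mean + Σ b_k · mode_k` with |b_k| ≤ 3·√λ_k, voxelized to a
homogeneous-density volume (bone = 700 HU, air = −1000 HU, 0.5 mm final
slice pitch) and rendered by trilinear ray casting.

## Worked example

```python
from fluorokin import SceneConfig, make_scene, simulate_interleaved_sequence
from fluorokin.tracking import track_sequence
from fluorokin.evaluation import mtre_series

scene = make_scene(SceneConfig(image_size=128), seed=1)
seq, truth = simulate_interleaved_sequence(scene, duration=0.3, seed=1)
result = track_sequence(scene.tibia_volume, seq, truth["tibia"][0],
                        scene.projections)
series = mtre_series(result.poses, truth["tibia"][:len(result.poses)],
                     scene.tibia, scene.tibia)
print(f"frames={len(result.poses)}  mmTRE={series.mmtre:.3f} mm  "
      f"pmTRE={series.pmtre:.3f} mm  all_success={series.success.all()}")
```

prints (exactly reproducible from the seed):

```
frames=17  mmTRE=0.097 mm  pmTRE=0.310 mm  all_success=True
```

i.e. over 17 interleaved frames of a flexing knee the tracked tibia pose
never deviates from ground truth by more than 0.31 mm of mean surface
distance — well inside the 1.5 mm registration-success threshold.

The same pipeline is scriptable from the shell:

```
fluorokin simulate --out scene/ --seed 1 --image-size 128 --duration 0.5
fluorokin track    --scene-dir scene/ --out poses.csv --bone tibia
fluorokin evaluate --scene-dir scene/ --poses poses.csv --bone tibia --out metrics.json
```

## Acceptance script

`scripts/acceptance.py` regenerates the headline tracking figure from
scratch: it builds the default 128×128 synthetic scene, simulates the full
2 s interleaved flexion–extension sequence (30 fps per plane, 1/60 s
inter-unit offset, σ = 2 gray-level noise), AIMT-tracks the ground-truth
tibia volume from the true first-frame pose, and writes the maximum
per-frame mTRE (mm) to JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
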