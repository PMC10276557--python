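"""High-level pipeline runs on synthetic scenes (shared by the CLI, the
test suite and the acceptance script)."""

from __future__ import annotations

import numpy as np

from .geometry import Pose6DOF, transform_to_pose, pose_to_transform
from .shape_recon import (ReconstructionSettings, derive_pair_transforms,
                          reconstruct_subject_model)
from .ssm import build_ssm, gpa_align
from .synthetic import (AcquisitionSet, SceneConfig, make_scene,
                        simulate_static_acquisitions, training_population)

PAIR_ANGLES = {1: (0.0,), 2: (0.0, 45.0), 3: (0.0, 30.0, 60.0)}


def reconstruct_synthetic_subject(
    seed: int = 0,
    n_pairs: int = 2,
    bone: str = "tibia",
    image_size: int = 128,
    settings: ReconstructionSettings | None = None,
    init_offset: np.ndarray | None = None,
    use_marker_transforms: bool = True,
):
    """Build an SSM from the scene's training population, then reconstruct
    the held-out subject from ``n_pairs`` static bi-plane pairs.

    The plate angles follow the static-calibration protocol: one pair at
    0 deg, two pairs at 0/45 deg, three at 0/30/60 deg. The initial pose
    guess is the truth perturbed by ``init_offset`` (default 3 mm / 3 deg,
    seeded) — standing in for a coarse manual initialization.

    Returns ``(mesh, pose, diagnostics)`` with surface RMSe diagnostics
    against the known truth mesh.
    """
    cfg = SceneConfig(image_size=image_size)
    scene = make_scene(cfg, seed=seed)
    ts, _, _ = training_population(scene, bone)
    aligned, _ = gpa_align(ts)
    model = build_ssm(aligned, n_modes=20)

    angles = PAIR_ANGLES[n_pairs]
    acq, obs, truth_T = simulate_static_acquisitions(
        scene, bone=bone, plate_angles=angles, seed=seed)
    if use_marker_transforms and n_pairs > 1:
        acq = AcquisitionSet(acq.pairs, acq.models,
                             derive_pair_transforms(obs, scene.projections))

    truth_pose = scene.bone_pose(bone, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1D1]))
    if init_offset is None:
        init_offset = rng.uniform(-3.0, 3.0, 6)
    init = Pose6DOF.from_vector(truth_pose.to_vector() + init_offset)

    settings = settings or ReconstructionSettings()
    truth_mesh = scene.tibia if bone == "tibia" else scene.femur
    return reconstruct_subject_model(model, acq, settings, init, truth_mesh=truth_mesh)
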