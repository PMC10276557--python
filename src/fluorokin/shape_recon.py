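"""Two-phase reconstruction of a subject-specific bone model from one or
more static bi-plane radiograph pairs.

Phase 1 searches jointly over the 6-DOF pose and the first 10 shape-mode
coefficients (bounded at +/-3 SD); phase 2 freezes those and refines
coefficients 11-20. Each candidate shape is synthesized from the shape
model, voxelized to a homogeneous-density pseudo-volume and compared to
every image by gradient correlation of its DRRs; the summed negative
similarity over all images is minimized by the seeded genetic algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .drr import VoxelVolume, generate_drr, silhouette_region, voxelize_mesh
from .geometry import Pose6DOF, RigidTransform, pose_to_transform, rigid_point_fit, triangulate_rsa
from .mesh import Mesh
from .registration import SearchSettings, ga_optimize, gradient_correlation
from .ssm import ShapeModel, synthesize_shape
from .synthetic import AcquisitionSet

__all__ = ["ReconstructionSettings", "derive_pair_transforms", "phase1_fit",
           "phase2_refine", "reconstruct_subject_model"]


@dataclass
class ReconstructionSettings:
    """Two-phase optimization configuration.

    ``ga_voxel_spacing`` is the coarse voxel pitch used while the genetic
    algorithm explores candidates; ``final_voxel_spacing`` (0.5 mm, the
    clinical slice pitch) is used for the final synthesized model's
    pseudo-volume.
    """

    phase1: SearchSettings = field(default_factory=lambda: SearchSettings(population=24, generations=14, seed=0))
    phase2: SearchSettings = field(default_factory=lambda: SearchSettings(population=16, generations=10, seed=1))
    n_modes_phase1: int = 10
    n_modes_phase2: int = 20
    pose_halfwidth: np.ndarray = field(
        default_factory=lambda: np.array([8.0, 8.0, 8.0, 8.0, 8.0, 8.0])
    )  # mm / deg around the initial pose guess
    ga_voxel_spacing: float = 1.0
    final_voxel_spacing: float = 0.5
    drr_step: float | None = None
    cache_decimals: int = 3  # coefficient rounding for the voxelization cache
    polish_evals_phase1: int = 400  # bounded Powell refinement after the GA
    polish_evals_phase2: int = 200


def derive_pair_transforms(marker_obs: np.ndarray, models) -> list[RigidTransform]:
    """Pair-to-pair rigid transforms from lead-marker observations.

    ``marker_obs``: (n_pairs, 2, M, 2) pixel coordinates of M markers in the
    two planes of each pair. Markers are triangulated per pair by
    radio-stereometric analysis and the clouds rigidly co-registered to
    pair 1. Returns one transform per pair (identity first) mapping pair-1
    coordinates into that pair's frame.
    """
    obs = np.asarray(marker_obs, float)
    if obs.ndim != 4 or obs.shape[1] != 2:
        raise ValueError("marker_obs must be (n_pairs, 2, M, 2)")
    if obs.shape[2] < 3:
        raise ValueError("need at least 3 markers visible in both planes")
    clouds = []
    for pair in obs:
        pts = [triangulate_rsa((pair[0, m], pair[1, m]), models)[0] for m in range(pair.shape[1])]
        clouds.append(np.array(pts))
    out = [RigidTransform.identity()]
    for cloud in clouds[1:]:
        T, _ = rigid_point_fit(clouds[0], cloud)
        out.append(T)
    return out


class _CandidateEvaluator:
    """Shared objective: summed -f_GC over all images of all pairs.

    Voxelizations are cached on the rounded shape-coefficient vector, so
    pose-only moves and GA re-visits of elite individuals are cheap.
    """

    def __init__(self, model: ShapeModel, acq: AcquisitionSet,
                 settings: ReconstructionSettings):
        self.model = model
        self.acq = acq
        self.s = settings
        self._cache: dict[tuple, VoxelVolume] = {}

    def volume_for(self, b: np.ndarray, spacing: float) -> VoxelVolume:
        key = (round(float(spacing), 6), tuple(np.round(b, self.s.cache_decimals)))
        vol = self._cache.get(key)
        if vol is None:
            mesh = synthesize_shape(self.model, b)
            vol = voxelize_mesh(mesh, spacing=spacing)
            if len(self._cache) > 512:
                self._cache.clear()
            self._cache[key] = vol
        return vol

    def cost(self, pose_vec: np.ndarray, b: np.ndarray, spacing: float | None = None) -> float:
        vol = self.volume_for(b, spacing or self.s.ga_voxel_spacing)
        T_pose = pose_to_transform(Pose6DOF.from_vector(pose_vec))
        total = 0.0
        for (img_a, img_b), T_pair in zip(self.acq.pairs, self.acq.pair_transforms):
            T = T_pair @ T_pose
            for img, proj in zip((img_a, img_b), self.acq.models):
                region = silhouette_region(vol, T, proj)
                drr = generate_drr(vol, T, proj, step=self.s.drr_step, region=region)
                total -= gradient_correlation(drr, img, region=region).f_gc
        return total


def phase1_fit(
    model: ShapeModel,
    acq: AcquisitionSet,
    settings: ReconstructionSettings,
    init_pose: Pose6DOF,
    evaluator: _CandidateEvaluator | None = None,
):
    """Joint 16-parameter search: 6-DOF pose + first 10 mode coefficients.

    The pose is bounded by ``settings.pose_halfwidth`` around ``init_pose``
    and each coefficient by +/-3 SD of its mode. Returns
    ``(Pose6DOF, coefficients[10], best_cost)``.
    """
    k1 = settings.n_modes_phase1
    if model.n_modes < k1:
        raise ValueError(f"shape model must retain at least {k1} modes")
    ev = evaluator or _CandidateEvaluator(model, acq, settings)
    x0 = init_pose.to_vector()
    blo, bhi = model.coefficient_bounds(k1)

    # coarse-to-fine: a pose-only search with the mean shape first (the mean
    # volume is voxelized once and cached, so these evaluations are cheap),
    # then the joint pose+shape search anchored at that pose
    zeros = np.zeros(k1)

    def pose_cost(x):
        return ev.cost(x, zeros)

    import dataclasses

    pose_ga = dataclasses.replace(settings.phase1, population=20, generations=10,
                                  seed=settings.phase1.seed + 11)
    pose_star, _, _ = ga_optimize(
        pose_cost, (x0 - settings.pose_halfwidth, x0 + settings.pose_halfwidth),
        pose_ga, initial=x0[None])

    lo = np.concatenate([x0 - settings.pose_halfwidth, blo])
    hi = np.concatenate([x0 + settings.pose_halfwidth, bhi])

    def cost(x):
        return ev.cost(x[:6], x[6:])

    # anchor the joint population on the pre-searched pose (plus jittered
    # copies sharing the cached mean-shape voxelization)
    rng = np.random.default_rng(settings.phase1.seed + 104729)
    n_anchor = min(10, settings.phase1.population // 2)
    anchors = [np.concatenate([pose_star, zeros]), np.concatenate([x0, zeros])]
    for _ in range(n_anchor - 2):
        jitter = rng.uniform(-0.3, 0.3, 6) * settings.pose_halfwidth
        anchors.append(np.concatenate([pose_star + jitter, zeros]))
    best_x, best_c, _ = ga_optimize(cost, (lo, hi), settings.phase1,
                                    initial=np.array(anchors))
    if settings.polish_evals_phase1:
        from scipy.optimize import minimize

        res = minimize(cost, best_x, method="Powell", bounds=list(zip(lo, hi)),
                       options={"maxfev": settings.polish_evals_phase1,
                                "xtol": 1e-3, "ftol": 1e-7})
        if res.fun < best_c:
            best_x, best_c = np.clip(res.x, lo, hi), float(res.fun)
    return Pose6DOF.from_vector(best_x[:6]), best_x[6:], best_c


def phase2_refine(
    model: ShapeModel,
    acq: AcquisitionSet,
    phase1_result,
    settings: ReconstructionSettings,
    evaluator: _CandidateEvaluator | None = None,
):
    """Refine coefficients 11..20 with pose and coefficients 1..10 frozen.

    The zero vector (i.e. the phase-1 solution) seeds the population, so
    the final objective can never exceed the phase-1 value. Returns
    ``(coefficients[20], best_cost)``.
    """
    k1, k2 = settings.n_modes_phase1, settings.n_modes_phase2
    if model.n_modes < k2:
        raise ValueError(f"shape model must retain at least {k2} modes")
    pose, b1, _ = phase1_result
    ev = evaluator or _CandidateEvaluator(model, acq, settings)
    pose_vec = pose.to_vector()
    blo, bhi = model.coefficient_bounds(k2)

    def cost(x):
        return ev.cost(pose_vec, np.concatenate([b1, x]))

    best_x, best_c, _ = ga_optimize(
        cost, (blo[k1:k2], bhi[k1:k2]), settings.phase2, initial=np.zeros(k2 - k1)[None]
    )
    if settings.polish_evals_phase2:
        from scipy.optimize import minimize

        res = minimize(cost, best_x, method="Powell",
                       bounds=list(zip(blo[k1:k2], bhi[k1:k2])),
                       options={"maxfev": settings.polish_evals_phase2,
                                "xtol": 1e-3, "ftol": 1e-7})
        if res.fun < best_c:
            best_x, best_c = np.clip(res.x, blo[k1:k2], bhi[k1:k2]), float(res.fun)
    return np.concatenate([b1, best_x]), best_c


def reconstruct_subject_model(
    model: ShapeModel,
    acq: AcquisitionSet,
    settings: ReconstructionSettings,
    init_pose: Pose6DOF,
    truth_mesh: Mesh | None = None,
):
    """Full two-phase reconstruction.

    Returns ``(mesh, pose, diagnostics)`` where ``diagnostics`` holds the
    per-phase best costs and, when a ground-truth mesh is supplied, the
    surface RMSe of the mean shape, the phase-1 shape and the final shape.
    """
    ev = _CandidateEvaluator(model, acq, settings)
    p1 = phase1_fit(model, acq, settings, init_pose, evaluator=ev)
    b20, c2 = phase2_refine(model, acq, p1, settings, evaluator=ev)
    mesh = synthesize_shape(model, b20)
    diag = {"phase1_cost": p1[2], "phase2_cost": c2,
            "coefficients": b20, "pose": p1[0]}
    if truth_mesh is not None:
        from .evaluation import shape_rmse

        diag["rmse_mean_shape"] = shape_rmse(model.mean_mesh(), truth_mesh)
        diag["rmse_phase1"] = shape_rmse(synthesize_shape(model, p1[1]), truth_mesh)
        diag["rmse_final"] = shape_rmse(mesh, truth_mesh)
    return mesh, p1[0], diag
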