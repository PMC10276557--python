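"""Accuracy metrics: point-to-surface distance, surface RMS error, target
registration error series and kinematic component differences.

The elementary quantity is the shortest Euclidean distance e(p, S) from a
point p to a triangulated surface S (exact point-to-triangle, not
vertex-only). Shape error (RMSe) is the RMS of e over all vertices of the
evaluated model after rigid ICP alignment; tracking error (mTRE) is the
mean of e per frame between the registered and truth-posed surfaces, with
its cycle mean (mmTRE), peak (pmTRE) and a per-frame success flag
(mTRE < 1.5 mm by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Pose6DOF, RigidTransform, pose_to_transform
from .kinematics import JointPose
from .mesh import Mesh, icp_rigid, point_triangle_distances

__all__ = ["ErrorSeries", "KinematicsDifference", "point_to_surface_distance",
           "shape_rmse", "mtre_series", "kinematics_mad_pad",
           "SUCCESS_THRESHOLD_MM"]

SUCCESS_THRESHOLD_MM = 1.5


@dataclass
class ErrorSeries:
    mtre: np.ndarray  # mm per frame
    threshold: float = SUCCESS_THRESHOLD_MM

    @property
    def mmtre(self) -> float:
        return float(self.mtre.mean())

    @property
    def pmtre(self) -> float:
        return float(self.mtre.max())

    @property
    def success(self) -> np.ndarray:
        return self.mtre < self.threshold


@dataclass
class KinematicsDifference:
    mad: np.ndarray  # (6,) mean absolute difference per component
    pad: np.ndarray  # (6,) peak absolute difference per component
    components: tuple = (
        "flexion_extension", "adduction_abduction", "internal_external",
        "medial_lateral", "anterior_posterior", "proximal_distal",
    )


def point_to_surface_distance(p, surface: Mesh, vertex_only: bool = False):
    """Shortest distance (mm) from point(s) ``p`` to the surface.

    ``vertex_only=True`` approximates by nearest-vertex distance (as some
    earlier work did); the default is the exact point-to-triangle minimum.
    """
    pts = np.atleast_2d(np.asarray(p, float))
    if surface.n_faces == 0 or surface.n_vertices == 0:
        raise ValueError("empty mesh")
    if vertex_only:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(surface.vertices).query(pts, k=1)
    else:
        d = point_triangle_distances(pts, surface)
    return d if np.asarray(p).ndim == 2 else float(d[0])


def shape_rmse(eval_mesh: Mesh, ref_mesh: Mesh, align: bool = True) -> float:
    """Surface RMS error of ``eval_mesh`` against ``ref_mesh`` (mm).

    Rigid ICP removes any global pose offset (unless ``align=False``), then
    the RMS of the point-to-surface distances of the evaluated model's
    vertices to the reference surface is returned. One-directional by
    construction (evaluated -> reference).
    """
    verts = eval_mesh.vertices
    if align:
        T, _ = icp_rigid(eval_mesh, ref_mesh)
        verts = T.apply(verts)
    d = point_triangle_distances(verts, ref_mesh)
    return float(np.sqrt(np.mean(d**2)))


def mtre_series(
    registered_poses: list[Pose6DOF | RigidTransform],
    truth_poses: list[Pose6DOF | RigidTransform],
    eval_mesh: Mesh,
    ref_surface: Mesh,
    threshold: float = SUCCESS_THRESHOLD_MM,
) -> ErrorSeries:
    """Per-frame mean target registration error between registered and truth
    poses.

    For each frame the evaluated mesh is placed at the registered pose and
    the reference surface at the truth pose; mTRE is the mean
    point-to-surface distance over all evaluated vertices. Computed
    equivalently in the reference model frame (truth^-1 o registered applied
    to the evaluated mesh) so the reference's spatial index is built once.
    """
    if len(registered_poses) != len(truth_poses):
        raise ValueError("pose series length mismatch")

    def as_T(p):
        return p if isinstance(p, RigidTransform) else pose_to_transform(p)

    out = np.empty(len(registered_poses))
    for i, (reg, tru) in enumerate(zip(registered_poses, truth_poses)):
        rel = as_T(tru).inverse() @ as_T(reg)
        pts = rel.apply(eval_mesh.vertices)
        out[i] = point_triangle_distances(pts, ref_surface).mean()
    return ErrorSeries(out, threshold)


def kinematics_mad_pad(
    series_a: list[JointPose],
    series_b: list[JointPose],
) -> KinematicsDifference:
    """Mean and peak absolute per-component differences of two joint-pose
    series over a motion cycle (deg for rotations, mm for translations)."""
    if len(series_a) != len(series_b):
        raise ValueError("series length mismatch")
    A = np.stack([j.to_vector() for j in series_a])
    B = np.stack([j.to_vector() for j in series_b])
    diff = np.abs(A - B)
    return KinematicsDifference(mad=diff.mean(axis=0), pad=diff.max(axis=0))
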