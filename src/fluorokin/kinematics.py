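"""Anatomical coordinate systems and joint kinematics.

The bone-fixed anatomical frame has x anterior, y superior, z to the right
(right-handed). Knee kinematics are the tibial frame expressed in the
femoral frame; rotations decompose by the intrinsic z-x-y Cardan sequence
into flexion/extension, adduction/abduction and internal/external rotation,
translations into medial/lateral (z), anterior/posterior (x) and
proximal/distal (y) components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Pose6DOF, RigidTransform, pose_to_transform, transform_to_cardan_zxy
from .mesh import Mesh, icp_rigid

__all__ = ["AnatomicalFrame", "JointPose", "define_acs", "transfer_acs", "joint_pose"]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Bone-fixed frame: ``origin`` (mm) and orthonormal ``axes`` whose
    columns are the x (anterior), y (superior), z (right) directions."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, columns = x, y, z

    def __post_init__(self):
        o = np.asarray(self.origin, float).reshape(3)
        A = np.asarray(self.axes, float).reshape(3, 3)
        if not np.allclose(A.T @ A, np.eye(3), atol=1e-8):
            raise ValueError("axes not orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("axes not right-handed")
        U, _, Vt = np.linalg.svd(A)
        object.__setattr__(self, "axes", U @ Vt)
        object.__setattr__(self, "origin", o)

    def as_transform(self) -> RigidTransform:
        """Transform mapping frame coordinates into the bone model frame."""
        return RigidTransform(self.axes, self.origin)

    def transformed(self, T: RigidTransform) -> "AnatomicalFrame":
        return AnatomicalFrame(T.apply(self.origin), T.rotation @ self.axes)


@dataclass(frozen=True)
class JointPose:
    flexion_extension: float  # deg, about femoral z
    adduction_abduction: float  # deg, about the floating x
    internal_external: float  # deg, about tibial y
    medial_lateral: float  # mm, along femoral z
    anterior_posterior: float  # mm, along femoral x
    proximal_distal: float  # mm, along femoral y

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.flexion_extension, self.adduction_abduction, self.internal_external,
            self.medial_lateral, self.anterior_posterior, self.proximal_distal,
        ])


def define_acs(mesh: Mesh, bone: str, hint_axes: np.ndarray | None = None) -> AnatomicalFrame:
    """Anatomical frame from the mesh geometry (deterministic stand-in for
    landmark-based definitions).

    Principal inertia axes of the vertices are labelled by proximity to the
    hint axes (identity by default, i.e. the mesh is roughly anatomically
    oriented: +y superior, +z right); the origin is the centroid of the
    articular 15% of vertices along the superior axis (distal end for the
    femur, proximal for the tibia).
    """
    if bone not in ("femur", "tibia"):
        raise ValueError("bone must be 'femur' or 'tibia'")
    V = mesh.vertices
    c = V.mean(axis=0)
    cov = np.cov((V - c).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[2] <= 0 or (evals[2] - evals[0]) / evals[2] < 0.05:
        raise ValueError("degenerate geometry: no distinguishable axes")
    hint = np.eye(3) if hint_axes is None else np.asarray(hint_axes, float)
    # greedily assign each anatomical direction the best-matching inertia axis
    axes = np.empty((3, 3))
    used = [False, False, False]
    for ai in (1, 2, 0):  # superior first, then right, anterior gets the rest
        scores = [abs(hint[:, ai] @ evecs[:, k]) if not used[k] else -1 for k in range(3)]
        k = int(np.argmax(scores))
        used[k] = True
        sign = np.sign(hint[:, ai] @ evecs[:, k]) or 1.0
        axes[:, ai] = sign * evecs[:, k]
    # exact right-handed orthonormal triad: x = y cross z
    y = axes[:, 1] / np.linalg.norm(axes[:, 1])
    z = axes[:, 2] - (axes[:, 2] @ y) * y
    z /= np.linalg.norm(z)
    x = np.cross(y, z)
    axes = np.stack([x, y, z], axis=1)

    h = V @ y
    if bone == "femur":  # articular surface is distal (low y)
        cut = np.quantile(h, 0.15)
        sel = h <= cut
    else:  # tibia: articular surface is proximal (high y)
        cut = np.quantile(h, 0.85)
        sel = h >= cut
    origin = V[sel].mean(axis=0)
    return AnatomicalFrame(origin, axes)


def transfer_acs(ct_mesh: Mesh, ct_frame: AnatomicalFrame, ssm_mesh: Mesh) -> AnatomicalFrame:
    """Carry the CT model's anatomical frame onto the reconstructed model.

    Rigidly co-registers the CT mesh to the reconstructed mesh by ICP and
    applies the same transform to the frame, avoiding discrepancies between
    independently computed frames.
    """
    T, _ = icp_rigid(ct_mesh, ssm_mesh)
    return ct_frame.transformed(T)


def joint_pose(
    femur_pose: Pose6DOF | RigidTransform,
    femur_frame: AnatomicalFrame,
    tibia_pose: Pose6DOF | RigidTransform,
    tibia_frame: AnatomicalFrame,
) -> JointPose:
    """Tibial anatomical frame expressed in the femoral anatomical frame.

    Both poses map each bone's model frame into the common laboratory
    frame. Gimbal lock in the Cardan decomposition propagates as
    :class:`~fluorokin.geometry.GimbalLockError`.
    """
    Tf = femur_pose if isinstance(femur_pose, RigidTransform) else pose_to_transform(femur_pose)
    Tt = tibia_pose if isinstance(tibia_pose, RigidTransform) else pose_to_transform(tibia_pose)
    F = Tf @ femur_frame.as_transform()  # femoral ACS -> lab
    T = Tt @ tibia_frame.as_transform()
    rel = F.inverse() @ T
    fe, aa, ie = transform_to_cardan_zxy(rel)
    dx, dy, dz = rel.translation
    return JointPose(
        flexion_extension=fe, adduction_abduction=aa, internal_external=ie,
        medial_lateral=float(dz), anterior_posterior=float(dx), proximal_distal=float(dy),
    )
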