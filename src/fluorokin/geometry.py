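"""Rigid transforms, pose parameterization, perspective projection and
radio-stereometric triangulation.

Conventions
-----------
* Lengths in millimetres, angles in **degrees** at every public boundary
  (radians only inside closed expressions).
* ``Pose6DOF`` rotations are *intrinsic* rotations applied in x -> y -> z
  order about the body's own axes; this parameterizes the six design
  variables of the registration cost and is deliberately distinct from the
  z-x-y Cardan sequence used to report joint angles.
* Pixels are 0-based with pixel centres on integer coordinates, ``u``
  rightward and ``v`` downward on the detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GimbalLockError",
    "RigidTransform",
    "Pose6DOF",
    "ProjectionModel",
    "pose_to_transform",
    "transform_to_pose",
    "cardan_zxy_compose",
    "transform_to_cardan_zxy",
    "rigid_point_fit",
    "triangulate_rsa",
    "wrap_angle_deg",
]

_ORTHO_TOL = 1e-9


class GimbalLockError(ValueError):
    """Raised when an Euler/Cardan decomposition is degenerate."""


def wrap_angle_deg(a):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        # re-orthonormalize to keep round-off below the 1e-9 invariant
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix()
        return cls(R, np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class Pose6DOF:
    """Six design variables of the registration search.

    ``x, y, z`` in mm; ``alpha, beta, gamma`` in degrees, interpreted as
    intrinsic rotations about the body x, then y, then z axes.
    """

    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            object.__setattr__(self, name, wrap_angle_deg(getattr(self, name)))

    @classmethod
    def from_vector(cls, v) -> "Pose6DOF":
        v = np.asarray(v, dtype=float).reshape(6)
        return cls(*v)

    def to_vector(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z, self.alpha, self.beta, self.gamma])

    def translation(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def pose_to_transform(pose: Pose6DOF) -> RigidTransform:
    """Build the rigid transform of a pose (intrinsic x-y-z rotation order)."""
    R = Rotation.from_euler(
        "XYZ", [pose.alpha, pose.beta, pose.gamma], degrees=True
    ).as_matrix()
    return RigidTransform(R, pose.translation())


def transform_to_pose(t: RigidTransform) -> Pose6DOF:
    """Invert :func:`pose_to_transform`; valid away from gimbal lock
    (|beta| = 90 deg)."""
    R = t.rotation
    # intrinsic XYZ: R[0,2] = sin(beta)
    if abs(abs(R[0, 2]) - 1.0) < 1e-12:
        raise GimbalLockError("beta = +/-90 deg: alpha/gamma indeterminate (y axis)")
    a, b, g = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
    return Pose6DOF(t.translation[0], t.translation[1], t.translation[2], a, b, g)


def cardan_zxy_compose(z_deg: float, x_deg: float, y_deg: float) -> np.ndarray:
    """Rotation matrix of intrinsic z -> x -> y Cardan angles (degrees)."""
    return Rotation.from_euler("ZXY", [z_deg, x_deg, y_deg], degrees=True).as_matrix()


def transform_to_cardan_zxy(t: RigidTransform | np.ndarray) -> tuple[float, float, float]:
    """Decompose a rotation into the z-x-y Cardan sequence used for joint
    angles (flexion about z, ad/abduction about x, int/external about y).

    Raises :class:`GimbalLockError` when the middle (x) angle reaches
    +/-90 deg, naming the degenerate axis.
    """
    R = t.rotation if isinstance(t, RigidTransform) else np.asarray(t, float)
    # intrinsic ZXY: R[2, 1] = sin(middle angle x)
    sx = R[2, 1]
    if abs(abs(sx) - 1.0) < 1e-10:
        raise GimbalLockError("middle Cardan angle at +/-90 deg (x axis degenerate)")
    z, x, y = Rotation.from_matrix(R).as_euler("ZXY", degrees=True)
    return float(z), float(x), float(y)


@dataclass(frozen=True)
class ProjectionModel:
    """Ideal point-source perspective projection of one X-ray unit.

    ``detector_origin`` is the 3D position of pixel (0, 0); pixel (u, v) has
    centre ``detector_origin + u*spacing_u*u_axis + v*spacing_v*v_axis``.
    """

    source: np.ndarray
    detector_origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    pixel_spacing: np.ndarray  # (su, sv) mm / pixel
    resolution: tuple[int, int]  # (nu, nv) pixels

    def __post_init__(self):
        for name in ("source", "detector_origin", "u_axis", "v_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        object.__setattr__(self, "pixel_spacing", np.asarray(self.pixel_spacing, float).reshape(2))
        object.__setattr__(self, "resolution", (int(self.resolution[0]), int(self.resolution[1])))
        u, v = self.u_axis, self.v_axis
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9:
            raise ValueError("u_axis / v_axis must be unit vectors")
        if abs(u @ v) > 1e-9:
            raise ValueError("u_axis and v_axis must be orthogonal")
        if self.source_detector_distance() <= 0:
            raise ValueError("source lies on the detector plane")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u_axis, self.v_axis)

    def source_detector_distance(self) -> float:
        return float(abs((self.source - self.detector_origin) @ self.normal))

    @property
    def principal_point(self) -> np.ndarray:
        """Pixel coordinates of the foot of the perpendicular from the source."""
        d = self.source - ((self.source - self.detector_origin) @ self.normal) * self.normal
        rel = d - self.detector_origin
        return np.array([rel @ self.u_axis, rel @ self.v_axis]) / self.pixel_spacing

    def principal_axis(self) -> np.ndarray:
        """Unit vector from the source toward the detector."""
        n = self.normal
        s = np.sign((self.detector_origin - self.source) @ n) or 1.0
        return s * n

    def project_points(self, points: np.ndarray) -> np.ndarray:
        """Perspective-project (N, 3) world points to (N, 2) pixel coords."""
        p = np.atleast_2d(np.asarray(points, float))
        n = self.normal
        denom = (p - self.source) @ n
        if np.any(np.abs(denom) < 1e-12):
            raise ValueError("ray parallel to the detector plane")
        lam = ((self.detector_origin - self.source) @ n) / denom
        hit = self.source + lam[:, None] * (p - self.source)
        rel = hit - self.detector_origin
        px = np.stack([rel @ self.u_axis, rel @ self.v_axis], axis=1) / self.pixel_spacing
        return px if np.asarray(points).ndim == 2 else px[0]

    def pixel_to_point(self, pixels: np.ndarray) -> np.ndarray:
        """3D position of pixel centre(s) on the detector plane."""
        px = np.atleast_2d(np.asarray(pixels, float))
        pts = (
            self.detector_origin
            + px[:, :1] * self.pixel_spacing[0] * self.u_axis
            + px[:, 1:2] * self.pixel_spacing[1] * self.v_axis
        )
        return pts if np.asarray(pixels).ndim == 2 else pts[0]

    def magnification_at(self, point: np.ndarray) -> float:
        """Geometric magnification for an object at ``point`` (SDD / SOD
        measured along the principal axis)."""
        ax = self.principal_axis()
        sod = float((np.asarray(point, float) - self.source) @ ax)
        if sod <= 0:
            raise ValueError("object behind the source")
        return self.source_detector_distance() / sod


def project_point(model: ProjectionModel, p) -> np.ndarray:
    """Module-level convenience wrapper around
    :meth:`ProjectionModel.project_points`."""
    return model.project_points(np.asarray(p, float))


def rigid_point_fit(src: np.ndarray, dst: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit (no scaling) mapping ``src`` onto ``dst``.

    Returns the transform and the residual RMS in mm.  Requires >= 3
    non-collinear correspondences (Kabsch / SVD solution).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (N, 3) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 correspondences")
    cs, cd = src.mean(0), dst.mean(0)
    A, B = src - cs, dst - cd
    s = np.linalg.svd(A, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) point configuration")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cd - R @ cs
    T = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((T.apply(src) - dst) ** 2, axis=1))))
    return T, rms


def triangulate_rsa(
    obs: tuple[np.ndarray, np.ndarray],
    models: tuple[ProjectionModel, ProjectionModel],
) -> tuple[np.ndarray, float]:
    """Radio-stereometric triangulation of one marker seen in two planes.

    ``obs`` holds the 2D pixel coordinates in each plane.  Returns the
    midpoint of the common perpendicular of the two back-projected rays and
    the residual (half the minimal inter-ray distance, mm).
    """
    o1, o2 = (np.asarray(o, float).reshape(2) for o in obs)
    m1, m2 = models
    p1, p2 = m1.source, m2.source
    d1 = m1.pixel_to_point(o1) - p1
    d2 = m2.pixel_to_point(o2) - p2
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2)
    cosang = np.clip(abs(d1 @ d2), 0.0, 1.0)
    if np.degrees(np.arccos(cosang)) < 1.0:
        raise ValueError("back-projected rays nearly parallel (< 1 deg)")
    # closed-form midpoint of the common perpendicular
    w0 = p1 - p2
    a, b, c = 1.0, d1 @ d2, 1.0
    d_, e_ = d1 @ w0, d2 @ w0
    denom = a * c - b * b
    s = (b * e_ - c * d_) / denom
    t = (a * e_ - b * d_) / denom
    q1 = p1 + s * d1
    q2 = p2 + t * d2
    point = 0.5 * (q1 + q2)
    residual = 0.5 * float(np.linalg.norm(q1 - q2))
    return point, residual
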