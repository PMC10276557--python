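"""Pseudo-volumetric bone models and digitally reconstructed radiographs.

A watertight surface mesh is converted to a homogeneous-density voxel volume
(interior = bone HU constant, exterior = air) and projected by ray casting
from the X-ray point source: per detector pixel, the line integral of
``value - air`` along the source->pixel ray, sampled with trilinear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import Pose6DOF, ProjectionModel, RigidTransform, pose_to_transform
from .mesh import Mesh

try:  # optional acceleration; the numpy path is the reference
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _integrate_rays_nb(values, ox, oy, oz, sx, sy, sz,
                           src, dirs, tmin, tmax, step):  # pragma: no cover
        n = dirs.shape[0]
        nx, ny, nz = values.shape
        out = np.zeros(n, dtype=np.float32)
        for r in range(n):
            t = tmin[r] + 0.5 * step
            acc = 0.0
            dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
            while t <= tmax[r]:
                px = (src[0] + t * dx - ox) / sx
                py = (src[1] + t * dy - oy) / sy
                pz = (src[2] + t * dz - oz) / sz
                i0 = int(np.floor(px)); j0 = int(np.floor(py)); k0 = int(np.floor(pz))
                if 0 <= i0 < nx - 1 and 0 <= j0 < ny - 1 and 0 <= k0 < nz - 1:
                    fx = px - i0; fy = py - j0; fz = pz - k0
                    c00 = values[i0, j0, k0] * (1 - fx) + values[i0 + 1, j0, k0] * fx
                    c10 = values[i0, j0 + 1, k0] * (1 - fx) + values[i0 + 1, j0 + 1, k0] * fx
                    c01 = values[i0, j0, k0 + 1] * (1 - fx) + values[i0 + 1, j0, k0 + 1] * fx
                    c11 = values[i0, j0 + 1, k0 + 1] * (1 - fx) + values[i0 + 1, j0 + 1, k0 + 1] * fx
                    c0 = c00 * (1 - fy) + c10 * fy
                    c1 = c01 * (1 - fy) + c11 * fy
                    acc += c0 * (1 - fz) + c1 * fz
                t += step
            out[r] = acc * step
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["VoxelVolume", "RadiographImage", "voxelize_mesh", "generate_drr",
           "BONE_HU", "AIR_HU"]

BONE_HU = 700.0  # homogeneous cortical-bone surrogate
AIR_HU = -1000.0


@dataclass
class VoxelVolume:
    """Axis-aligned voxel grid in the model frame.

    ``origin`` is the centre of voxel (0, 0, 0); ``values[i, j, k]`` sits at
    ``origin + (i, j, k) * spacing``.
    """

    origin: np.ndarray  # (3,) mm
    spacing: np.ndarray  # (3,) mm / voxel
    values: np.ndarray  # (nx, ny, nz) float32, HU
    air_value: float = AIR_HU

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        self.values = np.asarray(self.values, dtype=np.float32)

    @property
    def shape(self):
        return self.values.shape

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """AABB of the sampled region (voxel-centre extent) in mm."""
        return self.origin, self.origin + (np.array(self.shape) - 1) * self.spacing


@dataclass
class RadiographImage:
    """A single radiograph / fluoroscopy frame (float or 8-bit grayscale)."""

    pixels: np.ndarray  # (nv, nu) row = v (downward), col = u (rightward)
    plane_id: str = "A"
    timestamp: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)

    @property
    def shape(self):
        return self.pixels.shape

    def to_uint8(self) -> "RadiographImage":
        """Affine min-max normalization to 8-bit (per frame)."""
        p = self.pixels.astype(float)
        lo, hi = p.min(), p.max()
        scaled = np.zeros_like(p) if hi <= lo else (p - lo) / (hi - lo) * 255.0
        return RadiographImage(np.round(scaled).astype(np.uint8),
                               self.plane_id, self.timestamp, dict(self.meta))


# ------------------------------------------------------------- voxelization

def voxelize_mesh(
    mesh: Mesh,
    spacing: float | tuple = 0.5,
    bone_value: float = BONE_HU,
    air_value: float = AIR_HU,
    margin: float = 1.0,
) -> VoxelVolume:
    """Slice-parity voxelization of a watertight mesh.

    Voxel centres strictly inside the surface get ``bone_value`` (default
    700 HU), the rest ``air_value`` (default -1000 HU). Default spacing is
    0.5 mm isotropic. Parity is evaluated along +x grid lines per transverse
    (y, z) position, with a deterministic half-voxel offset applied to rays
    that graze a vertex or edge.
    """
    if mesh.n_faces == 0:
        raise ValueError("empty mesh cannot be voxelized")
    open_e = mesh.open_edges()
    if len(open_e):
        raise ValueError(f"mesh is not watertight; {len(open_e)} open edges: "
                         f"{open_e[:10].tolist()}...")
    spacing = np.asarray(np.broadcast_to(np.asarray(spacing, float), 3)).copy()
    lo, hi = mesh.bounds()
    origin = lo - margin
    n = np.ceil((hi - lo + 2 * margin) / spacing).astype(int) + 1
    values = np.full(n, air_value, dtype=np.float32)

    tri = mesh.triangles()  # (T,3,3)
    ny, nz = n[1], n[2]
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + spacing[2] * np.arange(nz)
    xs = origin[0] + spacing[0] * np.arange(n[0])

    t_ymin, t_ymax = tri[:, :, 1].min(1), tri[:, :, 1].max(1)
    t_zmin, t_zmax = tri[:, :, 2].min(1), tri[:, :, 2].max(1)

    # small deterministic offset avoids rays through vertices/edges
    eps_y = 0.5e-4 * spacing[1]
    eps_z = 0.37e-4 * spacing[2]

    # process one z-row of (y) lines at a time; pre-filter triangles by z
    for kz in range(nz):
        z = zs[kz] + eps_z
        sel = np.flatnonzero((t_zmin <= z) & (t_zmax >= z))
        if not len(sel):
            continue
        T = tri[sel]
        ymin, ymax = t_ymin[sel], t_ymax[sel]
        y = ys + eps_y  # (ny,)
        # candidate (line, triangle) pairs by y-overlap
        cand = (y[:, None] >= ymin[None, :]) & (y[:, None] <= ymax[None, :])
        li, ti = np.nonzero(cand)
        if not len(li):
            continue
        # 2D point-in-triangle in the (y, z) projection + x of intersection
        A, B, C = T[ti, 0], T[ti, 1], T[ti, 2]
        py, pz = y[li], z
        d = (B[:, 1] - C[:, 1]) * (A[:, 2] - C[:, 2]) - (B[:, 2] - C[:, 2]) * (A[:, 1] - C[:, 1])
        ok = np.abs(d) > 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            w1 = ((B[:, 1] - C[:, 1]) * (pz - C[:, 2]) - (B[:, 2] - C[:, 2]) * (py - C[:, 1])) / d
            w2 = ((C[:, 1] - A[:, 1]) * (pz - A[:, 2]) - (C[:, 2] - A[:, 2]) * (py - A[:, 1])) / d
            w3 = 1.0 - w1 - w2
        inside = ok & (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
        if not inside.any():
            continue
        li, w1, w2, w3 = li[inside], w1[inside], w2[inside], w3[inside]
        x_hit = w1 * A[inside, 0] + w2 * B[inside, 0] + w3 * C[inside, 0]
        # parity by flip accumulation: every crossing at x toggles all voxel
        # centres with centre >= x, i.e. from index ceil((x-o)/s). Centres in
        # the half-open [entry, exit) interval end up with odd parity —
        # entry-surface centres count as inside, exit-surface as outside
        # (deterministic, unbiased tie-break).
        i0 = np.ceil((x_hit - origin[0]) / spacing[0] - 1e-9).astype(np.int64)
        i0 = np.clip(i0, 0, n[0] - 1)
        flips = np.zeros((n[0], ny), dtype=np.int64)
        np.add.at(flips, (i0, li), 1)
        per_line = flips.sum(axis=0)
        inside_mask = (np.cumsum(flips, axis=0) % 2).astype(bool)
        inside_mask[:, per_line % 2 != 0] = False  # grazing leftovers
        values[:, :, kz][inside_mask] = bone_value
    return VoxelVolume(origin, spacing, values, air_value=air_value)


# ----------------------------------------------------------------- rendering

def generate_drr(
    volume: VoxelVolume,
    pose: Pose6DOF | RigidTransform,
    model: ProjectionModel,
    step: float | None = None,
    region: tuple[int, int, int, int] | None = None,
    as_uint8: bool = False,
) -> RadiographImage:
    """Render a DRR of ``volume`` posed by ``pose`` under ``model``.

    Per pixel the ray from the source through the pixel centre accumulates
    ``(value - air) * step`` with trilinear sampling. ``step`` defaults to
    half the smallest voxel spacing. ``region=(u0, u1, v0, v1)`` restricts
    rendering to a pixel window (full detector otherwise); pixels whose rays
    miss the volume are 0.
    """
    T = pose if isinstance(pose, RigidTransform) else pose_to_transform(pose)
    nu, nv = model.resolution
    if region is None:
        u0, u1, v0, v1 = 0, nu, 0, nv
    else:
        u0, u1, v0, v1 = region
        u0, v0 = max(u0, 0), max(v0, 0)
        u1, v1 = min(u1, nu), min(v1, nv)
    if step is None:
        step = 0.5 * float(volume.spacing.min())

    out = np.zeros((nv, nu), dtype=np.float32)
    if u1 <= u0 or v1 <= v0:
        return RadiographImage(out, meta={"region": (u0, u1, v0, v1)})

    uu, vv = np.meshgrid(np.arange(u0, u1), np.arange(v0, v1))
    pix = np.stack([uu.ravel(), vv.ravel()], axis=1).astype(float)
    targets = model.pixel_to_point(pix)  # (N,3) world

    # work in the volume's index frame: world -> model -> index
    Tinv = T.inverse()
    src_m = Tinv.apply(model.source)
    dirs = Tinv.apply(targets) - src_m
    lengths = np.linalg.norm(dirs, axis=1)
    dirs /= lengths[:, None]

    lo, hi = volume.bounds()
    # slab clipping per ray
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - src_m) / dirs
        t2 = (hi - src_m) / dirs
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    tmin = np.maximum(tmin, 0.0)
    hit = tmax > tmin
    if not hit.any():
        return RadiographImage(out, meta={"region": (u0, u1, v0, v1)})

    idx = np.flatnonzero(hit)
    tmin_h, tmax_h = tmin[idx], tmax[idx]
    shifted = volume.values - np.float32(volume.air_value)
    if _HAVE_NUMBA:
        integral = _integrate_rays_nb(
            np.ascontiguousarray(shifted),
            volume.origin[0], volume.origin[1], volume.origin[2],
            volume.spacing[0], volume.spacing[1], volume.spacing[2],
            src_m.astype(np.float64), np.ascontiguousarray(dirs[idx]),
            tmin_h, tmax_h, float(step),
        )
    else:
        n_steps = int(np.ceil((tmax_h - tmin_h).max() / step)) + 1
        ts = tmin_h[:, None] + step * (np.arange(n_steps)[None, :] + 0.5)
        valid = ts <= tmax_h[:, None]
        pts = src_m[None, None, :] + ts[..., None] * dirs[idx, None, :]
        coords = (pts - volume.origin) / volume.spacing  # index space
        # send invalid samples far outside the grid so they contribute 0
        coords[~valid] = -10.0
        flat = coords.reshape(-1, 3).T
        vals = map_coordinates(
            shifted, flat, order=1, mode="constant", cval=0.0, prefilter=False,
        ).reshape(len(idx), n_steps)
        integral = vals.sum(axis=1) * step
    acc = np.zeros(len(pix), dtype=np.float32)
    acc[idx] = integral.astype(np.float32)
    out[v0:v1, u0:u1] = acc.reshape(v1 - v0, u1 - u0)
    img = RadiographImage(out, meta={"region": (u0, u1, v0, v1)})
    return img.to_uint8() if as_uint8 else img


def silhouette_region(
    volume: VoxelVolume,
    pose: Pose6DOF | RigidTransform,
    model: ProjectionModel,
    dilate: int = 10,
) -> tuple[int, int, int, int]:
    """Pixel bounding box of the posed volume AABB's projection, dilated.

    Used as the similarity-evaluation window; the eight AABB corners bound
    the true silhouette for a convex frustum.
    """
    T = pose if isinstance(pose, RigidTransform) else pose_to_transform(pose)
    lo, hi = volume.bounds()
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    px = model.project_points(T.apply(corners))
    nu, nv = model.resolution
    u0 = int(np.floor(px[:, 0].min())) - dilate
    u1 = int(np.ceil(px[:, 0].max())) + dilate + 1
    v0 = int(np.floor(px[:, 1].min())) - dilate
    v1 = int(np.ceil(px[:, 1].max())) + dilate + 1
    return max(u0, 0), min(u1, nu), max(v0, 0), min(v1, nv)
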