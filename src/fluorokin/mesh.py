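"""Triangulated surface meshes: container, ASCII PLY/STL I/O, closest-point
queries and rigid ICP.

Vertices are in millimetres. Faces are (F, 3) int vertex-index triples with
consistent outward winding. Watertightness (every edge shared by exactly two
faces) is required only where interior/exterior labelling is needed
(voxelization).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Mesh", "ICPDivergence", "icp_rigid", "point_triangle_distances"]


class ICPDivergence(RuntimeError):
    """Rigid ICP failed to converge (distance increased repeatedly)."""


@dataclass
class Mesh:
    vertices: np.ndarray  # (V, 3) float, mm
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    # ------------------------------------------------------------------ basics
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "Mesh":
        return Mesh(self.vertices.copy(), self.faces.copy())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def transformed(self, transform) -> "Mesh":
        return Mesh(transform.apply(self.vertices), self.faces)

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def open_edges(self) -> np.ndarray:
        """Edges not shared by exactly two faces ((K, 2) vertex index pairs)."""
        if not len(self.faces):
            return np.zeros((0, 2), dtype=np.int64)
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts != 2]

    def is_watertight(self) -> bool:
        return len(self.faces) > 0 and len(self.open_edges()) == 0

    def face_normals(self) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    # -------------------------------------------------------------------- I/O
    def save(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".ply":
            _write_ply(self, path)
        elif path.suffix.lower() == ".stl":
            _write_stl(self, path)
        else:
            raise ValueError(f"unsupported mesh format: {path.suffix}")

    @classmethod
    def load(cls, path) -> "Mesh":
        path = Path(path)
        if path.suffix.lower() == ".ply":
            return _read_ply(path)
        if path.suffix.lower() == ".stl":
            return _read_stl(path)
        raise ValueError(f"unsupported mesh format: {path.suffix}")


# ---------------------------------------------------------------- PLY / STL

def _write_ply(mesh: Mesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_ply(path: Path) -> Mesh:
    with open(path) as fh:
        if fh.readline().strip() != "ply":
            raise ValueError("not a PLY file")
        fmt = fh.readline().strip()
        if "ascii" not in fmt:
            raise ValueError("only ASCII PLY is supported")
        n_vert = n_face = 0
        line = fh.readline()
        while line and line.strip() != "end_header":
            tok = line.split()
            if tok[:2] == ["element", "vertex"]:
                n_vert = int(tok[2])
            elif tok[:2] == ["element", "face"]:
                n_face = int(tok[2])
            line = fh.readline()
        verts = np.array([fh.readline().split()[:3] for _ in range(n_vert)], dtype=float)
        faces = []
        for _ in range(n_face):
            tok = fh.readline().split()
            if int(tok[0]) != 3:
                raise ValueError("only triangle faces are supported")
            faces.append(tok[1:4])
        return Mesh(verts, np.array(faces, dtype=np.int64) if faces else np.zeros((0, 3), int))


def _write_stl(mesh: Mesh, path: Path) -> None:
    normals = mesh.face_normals()
    tri = mesh.triangles()
    with open(path, "w") as fh:
        fh.write("solid fluorokin\n")
        for n, t in zip(normals, tri):
            fh.write(f"facet normal {n[0]:.10g} {n[1]:.10g} {n[2]:.10g}\n outer loop\n")
            for c in t:
                fh.write(f"  vertex {c[0]:.10g} {c[1]:.10g} {c[2]:.10g}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid fluorokin\n")


def _read_stl(path: Path) -> Mesh:
    """ASCII STL reader; vertices merged exactly (bitwise equal coordinates)."""
    coords = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if tok and tok[0] == "vertex":
                coords.append([float(tok[1]), float(tok[2]), float(tok[3])])
    coords = np.array(coords).reshape(-1, 3, 3)
    flat = coords.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    return Mesh(uniq, inverse.reshape(-1, 3))


# ---------------------------------------------------- point-triangle distance

def _project_to_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact squared distances from each point to each triangle.

    ``points``: (N, 3); ``tri``: (T, 3, 3). Returns (N, T). Standard
    barycentric region classification, fully vectorized.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a  # (T,3)
    ac = c - a
    ap = points[:, None, :] - a[None, :, :]  # (N,T,3)

    d1 = np.einsum("ntk,tk->nt", ap, ab)
    d2 = np.einsum("ntk,tk->nt", ap, ac)
    bp = points[:, None, :] - b[None, :, :]
    d3 = np.einsum("ntk,tk->nt", bp, ab)
    d4 = np.einsum("ntk,tk->nt", bp, ac)
    cp = points[:, None, :] - c[None, :, :]
    d5 = np.einsum("ntk,tk->nt", cp, ab)
    d6 = np.einsum("ntk,tk->nt", cp, ac)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    shape = d1.shape
    closest = np.zeros(shape + (3,))
    assigned = np.zeros(shape, dtype=bool)

    def assign(mask, cand):
        nonlocal assigned
        m = mask & ~assigned
        closest[m] = cand[m] if cand.shape == closest.shape else np.broadcast_to(cand, closest.shape)[m]
        assigned = assigned | m

    # region tests in Ericson's sequential order (Real-Time Collision
    # Detection 5.1.5): each test assumes all previous ones failed.
    assign((d1 <= 0) & (d2 <= 0), np.broadcast_to(a[None], closest.shape))  # vertex A
    assign((d3 >= 0) & (d4 <= d3), np.broadcast_to(b[None], closest.shape))  # vertex B
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 != d3, d1 / (d1 - d3), 0.0)
    assign(
        (vc <= 0) & (d1 >= 0) & (d3 <= 0),
        a[None] + np.clip(v_ab, 0, 1)[..., None] * ab[None],
    )  # edge AB
    assign((d6 >= 0) & (d5 <= d6), np.broadcast_to(c[None], closest.shape))  # vertex C
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 != d6, d2 / (d2 - d6), 0.0)
    assign(
        (vb <= 0) & (d2 >= 0) & (d6 <= 0),
        a[None] + np.clip(w_ac, 0, 1)[..., None] * ac[None],
    )  # edge AC
    with np.errstate(divide="ignore", invalid="ignore"):
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
    assign(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
        b[None] + np.clip(w_bc, 0, 1)[..., None] * (c - b)[None],
    )  # edge BC
    with np.errstate(divide="ignore", invalid="ignore"):
        den = va + vb + vc
        v_in = np.where(den != 0, vb / den, 0.0)
        w_in = np.where(den != 0, vc / den, 0.0)
    assign(
        np.ones(shape, dtype=bool),
        a[None] + v_in[..., None] * ab[None] + w_in[..., None] * ac[None],
    )  # interior

    diff = points[:, None, :] - closest
    return np.einsum("ntk,ntk->nt", diff, diff)


def point_triangle_distances(points: np.ndarray, mesh: Mesh, chunk: int = 256) -> np.ndarray:
    """Exact minimum Euclidean distance from each point to the mesh surface.

    A KD-tree over triangle centroids prunes candidates with a provable
    bound (nearest-centroid distance + largest triangle circumradius), then
    exact point-triangle distances decide. Equals the brute-force
    over-all-triangles minimum.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if mesh.n_faces == 0:
        raise ValueError("empty mesh")
    tri = mesh.triangles()
    centroids = tri.mean(axis=1)
    rad = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        pts = points[s : s + chunk]
        dmin, _ = tree.query(pts, k=1)
        # any triangle whose centroid is farther than dmin + 2*rad cannot win
        groups = tree.query_ball_point(pts, dmin + 2.0 * rad + 1e-12)
        for i, idx in enumerate(groups):
            d2 = _project_to_triangles(pts[i : i + 1], tri[np.asarray(idx)])
            out[s + i] = np.sqrt(d2.min())
    return out


# ------------------------------------------------------------------ rigid ICP

def _pca_init(src: np.ndarray, dst: np.ndarray):
    """Coarse alignment from principal axes, used to start ICP inside its
    basin of convergence. Axis signs are ambiguous, so all four proper
    combinations are scored by nearest-neighbour RMS and the best kept."""
    from .geometry import RigidTransform

    cs, cd = src.mean(0), dst.mean(0)

    def frame(pts, c):
        _, vecs = np.linalg.eigh(np.cov((pts - c).T))
        vecs = np.ascontiguousarray(vecs[:, ::-1])  # descending variance
        if np.linalg.det(vecs) < 0:
            vecs[:, 2] = -vecs[:, 2]
        return vecs

    Fs, Fd = frame(src, cs), frame(dst, cd)
    tree = cKDTree(dst)
    sample = src[:: max(1, len(src) // 200)]
    best = None
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([s1, s2, s1 * s2])  # proper rotations only
        R = Fd @ S @ Fs.T
        t = cd - R @ cs
        d, _ = tree.query(sample @ R.T + t, k=1)
        score = float(np.sqrt(np.mean(d**2)))
        if best is None or score < best[0]:
            best = (score, R, t)
    return RigidTransform(best[1], best[2])

def icp_rigid(
    source: Mesh | np.ndarray,
    target: Mesh,
    max_iterations: int = 60,
    tol: float = 1e-7,
    trim: float = 0.95,
    init=None,
):
    """Rigid point-to-point ICP aligning ``source`` onto ``target``.

    Closest-vertex matching against the target vertices with trimming of the
    worst ``1-trim`` fraction (ties broken by lowest vertex index, which is
    cKDTree's deterministic behaviour). Returns ``(RigidTransform, rms)``.

    Raises :class:`ICPDivergence` if the trimmed RMS increases for five
    consecutive iterations.
    """
    from .geometry import RigidTransform, rigid_point_fit

    src_pts = source.vertices if isinstance(source, Mesh) else np.asarray(source, float)
    T = init if init is not None else _pca_init(src_pts, target.vertices)
    tree = cKDTree(target.vertices)
    prev_rms = np.inf
    best: tuple[RigidTransform, float] | None = None
    bad = 0
    for _ in range(max_iterations):
        moved = T.apply(src_pts)
        d, j = tree.query(moved, k=1)
        keep = np.argsort(d, kind="stable")[: max(3, int(np.ceil(trim * len(d))))]
        T_new, _ = rigid_point_fit(src_pts[keep], target.vertices[j[keep]])
        T = T_new
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        if best is None or rms < best[1]:
            best = (T, rms)
        if rms > prev_rms + 1e-12:
            bad += 1
            if bad >= 5:
                raise ICPDivergence("ICP distance increased for 5 iterations")
        else:
            bad = 0
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    return best[0], best[1]
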