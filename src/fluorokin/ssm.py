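"""Statistical shape modelling: mesh correspondence, generalized Procrustes
alignment, PCA mode extraction and shape synthesis.

A shape model is a mean shape (3V-vector, mm) plus M orthonormal variation
modes with eigenvalues (mm^2). Coefficients are stored on the raw mm scale;
optimizers bound mode k by +/-3 sqrt(eigenvalue_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, rigid_point_fit
from .mesh import ICPDivergence, Mesh, icp_rigid, point_triangle_distances

__all__ = ["TrainingSet", "ShapeModel", "establish_correspondence", "gpa_align",
           "build_ssm", "synthesize_shape"]


@dataclass
class TrainingSet:
    """Corresponded training meshes (identical topology)."""

    shapes: list[Mesh]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = [f"shape{i:03d}" for i in range(len(self.shapes))]
        if len(self.shapes) >= 2:
            f0 = self.shapes[0].faces
            for s in self.shapes[1:]:
                if s.n_vertices != self.shapes[0].n_vertices or not np.array_equal(s.faces, f0):
                    raise ValueError("training shapes must share the reference topology")

    def __len__(self):
        return len(self.shapes)

    def data_matrix(self) -> np.ndarray:
        """(n, 3V) stacked vertex-coordinate vectors."""
        return np.stack([s.vertices.ravel() for s in self.shapes])


@dataclass
class ShapeModel:
    mean_shape: np.ndarray  # (3V,)
    modes: np.ndarray  # (3V, M), orthonormal columns
    eigenvalues: np.ndarray  # (M,), mm^2, descending
    topology: np.ndarray  # (F, 3)

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, float).ravel()
        self.modes = np.asarray(self.modes, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float).ravel()
        G = self.modes.T @ self.modes
        if not np.allclose(G, np.eye(self.modes.shape[1]), atol=1e-8):
            raise ValueError("mode columns are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_vertices(self) -> int:
        return len(self.mean_shape) // 3

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def mean_mesh(self) -> Mesh:
        return Mesh(self.mean_shape.reshape(-1, 3), self.topology)

    def coefficient_bounds(self, n_modes: int | None = None, n_sd: float = 3.0):
        """(lo, hi) arrays bounding each coefficient at +/- n_sd standard
        deviations."""
        k = self.n_modes if n_modes is None else n_modes
        sd = np.sqrt(np.maximum(self.eigenvalues[:k], 0.0))
        return -n_sd * sd, n_sd * sd

    def save(self, path) -> None:
        np.savez_compressed(Path(path), mean_shape=self.mean_shape, modes=self.modes,
                            eigenvalues=self.eigenvalues, topology=self.topology)

    @classmethod
    def load(cls, path) -> "ShapeModel":
        with np.load(Path(path)) as z:
            return cls(z["mean_shape"], z["modes"], z["eigenvalues"], z["topology"])


# ------------------------------------------------------------ correspondence

def establish_correspondence(
    reference: Mesh,
    target: Mesh,
    iterations: int = 30,
    kernel_frac: float = 0.10,
    step: float = 0.8,
) -> tuple[Mesh, float]:
    """Deform the reference mesh onto the target surface.

    Rigid ICP pre-alignment followed by a Gaussian-kernel-regularized
    nonrigid registration: at each iteration the closest-target-vertex
    residual field is smoothed by a Gaussian kernel over the reference
    vertices (width = ``kernel_frac`` of the bounding-box diagonal) and a
    fraction ``step`` of it is applied. Returns the corresponded mesh (the
    reference's connectivity on the target's geometry) and the mean
    vertex-to-target-surface distance (mm).
    """
    T, _ = icp_rigid(reference, target)
    current = T.apply(reference.vertices)

    lo, hi = target.bounds()
    sigma = kernel_frac * float(np.linalg.norm(hi - lo))
    tree = cKDTree(target.vertices)
    # fixed smoothing weights over the pre-aligned reference vertices
    d2 = np.sum((current[:, None, :] - current[None, :, :]) ** 2, axis=2)
    W = np.exp(-d2 / (2.0 * sigma**2))
    W /= W.sum(axis=1, keepdims=True)
    for it in range(iterations):
        _, j = tree.query(current, k=1)
        resid = target.vertices[j] - current
        current = current + step * (W @ resid)
        # anneal the kernel: halve sigma twice over the schedule
        if it in (iterations // 3, 2 * iterations // 3):
            sigma *= 0.5
            W = np.exp(-d2 / (2.0 * sigma**2))
            W /= W.sum(axis=1, keepdims=True)
    out = Mesh(current, reference.faces)
    mean_dist = float(point_triangle_distances(current, target).mean())
    return out, mean_dist


# ------------------------------------------------------------------- GPA

def gpa_align(
    shapes: TrainingSet,
    with_scale: bool = False,
    tol: float = 1e-6,
    max_iterations: int = 100,
) -> tuple[TrainingSet, np.ndarray]:
    """Generalized Procrustes alignment (translation + rotation; scale
    removal optional and off by default — bone size is a shape feature).

    Iterates rigid fits to the evolving mean until the mean moves less than
    ``tol`` mm. Returns the aligned set and the converged mean (V, 3).
    """
    if len(shapes) < 2:
        raise ValueError("need at least two shapes")
    X = [s.vertices - s.vertices.mean(0) for s in shapes.shapes]
    mean = X[0].copy()
    for _ in range(max_iterations):
        aligned = []
        for v in X:
            src = v
            if with_scale:
                src = src * (np.linalg.norm(mean) / np.linalg.norm(src))
            T, _ = rigid_point_fit(src, mean)
            aligned.append(T.apply(src))
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        X = aligned
        mean = new_mean
        if shift < tol:
            break
    faces = shapes.shapes[0].faces
    return TrainingSet([Mesh(v, faces) for v in X], list(shapes.labels)), mean


# ------------------------------------------------------------------- PCA

def build_ssm(aligned: TrainingSet, n_modes: int | None = None) -> ShapeModel:
    """PCA of the aligned training set about its mean.

    ``n_modes`` defaults to 20 (or n-1 if smaller), mirroring the two-phase
    10 + 10 reconstruction split. Raises if ``n_modes`` exceeds n-1.
    """
    X = aligned.data_matrix()
    n = len(X)
    if n_modes is None:
        n_modes = min(20, n - 1)
    if n_modes > n - 1:
        raise ValueError(f"n_modes={n_modes} exceeds maximal rank {n - 1}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    modes = Vt[:n_modes].T
    return ShapeModel(mean, modes, eigenvalues[:n_modes], aligned.shapes[0].faces)


def synthesize_shape(model: ShapeModel, coeffs: np.ndarray) -> Mesh:
    """Mean shape plus a linear combination of the leading modes."""
    b = np.asarray(coeffs, float).ravel()
    if len(b) > model.n_modes:
        raise ValueError("more coefficients than retained modes")
    v = model.mean_shape + model.modes[:, : len(b)] @ b
    return Mesh(v.reshape(-1, 3), model.topology)


def fit_coefficients(model: ShapeModel, mesh: Mesh, n_modes: int | None = None) -> np.ndarray:
    """Least-squares projection of a corresponded mesh onto the mode basis."""
    k = model.n_modes if n_modes is None else n_modes
    resid = mesh.vertices.ravel() - model.mean_shape
    return model.modes[:, :k].T @ resid
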