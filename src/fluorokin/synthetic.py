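"""Synthetic ground-truth generator: procedural bone-shape populations,
orthogonal bi-plane X-ray geometry, static multi-view acquisitions with lead
markers, and interleaved dynamic sequences.

The bone analogs are procedural (superellipsoid-like shafts with condyle /
plateau lobes), not anatomical: every downstream stage is evaluated by
parameter recovery against the generator's known truth, so the shapes only
need enough asymmetry to pin down an anatomical frame and break silhouette
ambiguities. Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .drr import AIR_HU, BONE_HU, RadiographImage, VoxelVolume, generate_drr, voxelize_mesh
from .geometry import Pose6DOF, ProjectionModel, RigidTransform, pose_to_transform
from .mesh import Mesh
from .ssm import TrainingSet

__all__ = ["SceneConfig", "SyntheticScene", "icosphere", "base_bone_mesh",
           "generate_bone_population", "make_scene",
           "simulate_static_acquisitions", "simulate_interleaved_sequence",
           "AcquisitionSet", "InterleavedSequence"]


# ------------------------------------------------------------------ meshes

def icosphere(subdivisions: int = 3) -> Mesh:
    """Unit icosphere by recursive icosahedron subdivision (watertight)."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ])
    for _ in range(subdivisions):
        verts_list = list(verts)
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return Mesh(verts, faces)


def _gauss_dir(d, center, width):
    """Gaussian bump over unit directions d (N,3) centred at unit vector."""
    c = np.asarray(center, float)
    c = c / np.linalg.norm(c)
    return np.exp(-np.sum((d - c) ** 2, axis=1) / (2.0 * width**2))


def base_bone_mesh(bone: str = "femur", subdivisions: int = 3, size: float = 30.0) -> Mesh:
    """Procedural distal-femur / proximal-tibia analog.

    Radial deformation of an icosphere: an anisotropically scaled body with
    two condyle-like lobes (femur, on the distal -y side, offset in +/-z)
    or a flattened plateau with a shaft stub (tibia). An anterior (+x) bump
    breaks the front/back symmetry so an anatomical frame is well defined.
    ``size`` is the base radius in mm.
    """
    sph = icosphere(subdivisions)
    d = sph.vertices  # unit directions
    r = np.full(len(d), 1.0)
    if bone == "femur":
        # two posterior-distal condyle lobes, left and right
        r += 0.55 * _gauss_dir(d, [0.0, -0.8, 0.55], 0.45)
        r += 0.55 * _gauss_dir(d, [0.0, -0.8, -0.55], 0.45)
        r += 0.18 * _gauss_dir(d, [1.0, 0.3, 0.0], 0.5)  # anterior (trochlea-like)
        scale = np.array([0.75, 1.05, 1.0])
    elif bone == "tibia":
        r += 0.35 * _gauss_dir(d, [0.0, 1.0, 0.45], 0.5)   # medial plateau lobe
        r += 0.35 * _gauss_dir(d, [0.0, 1.0, -0.45], 0.5)  # lateral plateau lobe
        r += 0.25 * _gauss_dir(d, [0.7, 0.7, 0.0], 0.35)   # tuberosity-like bump
        scale = np.array([0.7, 1.15, 0.95])
    else:
        raise ValueError("bone must be 'femur' or 'tibia'")
    verts = d * r[:, None] * size * scale
    return Mesh(verts, sph.faces)


def _make_modes(base: Mesh, k: int, rng: np.random.Generator) -> np.ndarray:
    """k orthonormal smooth displacement fields (3V, k), orthogonal to the
    rigid-motion subspace so they are pure shape (not pose) variation."""
    V = base.vertices
    d = V / np.linalg.norm(V, axis=1, keepdims=True)
    # 6-dim linearized rigid subspace: 3 translations + 3 rotations about
    # the centroid
    c = V.mean(axis=0)
    rigid = []
    for ax in np.eye(3):
        rigid.append(np.tile(ax, len(V)))
        rigid.append(np.cross(ax, V - c).ravel())
    fields = []
    for _ in range(k):
        f = np.zeros_like(V)
        for _ in range(3):  # sum of three random smooth radial bumps
            centre = rng.normal(size=3)
            width = rng.uniform(0.35, 0.8)
            amp = rng.normal()
            f += amp * _gauss_dir(d, centre, width)[:, None] * d
        fields.append(f.ravel())
    M = np.stack(rigid + fields, axis=1)  # (3V, 6 + k)
    Q, _ = np.linalg.qr(M)
    return Q[:, 6 : 6 + k]


# per-mode SD of the surface displacement each mode contributes, expressed
# as per-vertex RMS in mm; leading mode 1.5 mm, geometrically decaying. The
# resulting subject-vs-mean surface RMS (~2-3 mm) matches the shape
# variability real bone SSMs must absorb.
DEFAULT_MODE_SDS = 1.5 * 0.8 ** np.arange(24)


def generate_bone_population(
    n: int = 60,
    k: int = 20,
    seed: int = 0,
    bone: str = "femur",
    subdivisions: int = 3,
    mode_sds: np.ndarray | None = None,
    extra: int = 0,
):
    """Population of corresponded bone shapes from k known smooth modes.

    Defaults mirror a 60-knee training database. Weights are seeded
    Gaussians with per-mode SD ``mode_sds`` (mm, decaying by default).
    Returns ``(TrainingSet, modes (3V, k), weights (n+extra, k))``; the
    ``extra`` trailing shapes are held-out subjects never used for training.
    """
    if n < 3:
        raise ValueError("population needs n >= 3")
    rng = np.random.default_rng(seed)
    base = base_bone_mesh(bone, subdivisions)
    modes = _make_modes(base, k, rng)
    sds = np.asarray(mode_sds if mode_sds is not None else DEFAULT_MODE_SDS[:k], float)[:k]
    # modes are unit-norm over the 3V stacked coordinates, so a weight of
    # sqrt(V) produces 1 mm per-vertex RMS displacement
    weights = rng.normal(size=(n + extra, k)) * sds * np.sqrt(base.n_vertices)
    shapes = [
        Mesh((base.vertices.ravel() + modes @ w).reshape(-1, 3), base.faces)
        for w in weights[:n]
    ]
    return TrainingSet(shapes), modes, weights


# ------------------------------------------------------------------- scene

@dataclass
class SceneConfig:
    """Stated world of the synthetic knee scene.

    Defaults mirror the clinical setup: orthogonal detector units, 512x512
    8-bit frames, 30 fps per plane with a 1/60 s inter-unit offset, and a
    sinusoidal 0-60 degree flexion-extension cycle. ``image_size`` is
    reduced (e.g. to 128) for desk-scale runs.
    """

    image_size: int = 512
    detector_width: float = 256.0  # mm
    source_isocenter: float = 820.0  # mm
    source_detector: float = 1000.0  # mm
    flexion_amplitude: float = 60.0  # deg
    motion_period: float = 2.0  # s
    joint_gap: float = 10.0  # mm between femoral and tibial analogs
    bone_size: float = 30.0  # mm base radius
    n_markers: int = 6
    population_n: int = 60
    population_k: int = 20
    subdivisions: int = 3
    noise_sigma: float = 2.0  # gray levels (8-bit scale)
    voxel_spacing: float = 1.0  # mm, truth volumes
    motion_type: str = "flexion"  # or "constant_velocity"
    velocity: tuple = (60.0, 0.0, 0.0)  # mm/s tibia drift (constant-velocity mode);
    # 60 mm/s matches the peak tibial-centroid speed of the flexion cycle


@dataclass
class SyntheticScene:
    config: SceneConfig
    seed: int
    femur: Mesh
    tibia: Mesh
    femur_volume: VoxelVolume
    tibia_volume: VoxelVolume
    projections: tuple[ProjectionModel, ProjectionModel]
    marker_positions: np.ndarray  # (M, 3) lab frame at t=0
    base_poses: dict  # bone -> Pose6DOF at t=0

    def flexion_angle(self, t: float) -> float:
        c = self.config
        return 0.5 * c.flexion_amplitude * (1.0 - np.cos(2.0 * np.pi * t / c.motion_period))

    def bone_pose(self, bone: str, t: float) -> Pose6DOF:
        """Ground-truth pose of a bone's model frame in the lab at time t.

        The femur stands still; the tibia rotates about the lab z axis
        through the joint centre (flexion), carrying its base pose along.
        """
        base = self.base_poses[bone]
        if bone == "femur":
            return base
        if self.config.motion_type == "constant_velocity":
            v = np.asarray(self.config.velocity, float)
            return Pose6DOF.from_vector(
                base.to_vector() + np.concatenate([v * t, np.zeros(3)]))
        theta = self.flexion_angle(t)
        R = RigidTransform.from_rotvec_deg([0.0, 0.0, -theta])
        T = R @ pose_to_transform(base)
        from .geometry import transform_to_pose

        return transform_to_pose(T)

    def render_frame(self, plane: int, t: float, rng=None) -> RadiographImage:
        """Render the 8-bit fluoro frame of both bones at time t on a plane."""
        model = self.projections[plane]
        acc = None
        for bone, vol in (("femur", self.femur_volume), ("tibia", self.tibia_volume)):
            drr = generate_drr(vol, self.bone_pose(bone, t), model)
            acc = drr.pixels if acc is None else acc + drr.pixels
        img = RadiographImage(acc, plane_id="AB"[plane], timestamp=t)
        img = img.to_uint8()
        if rng is not None and self.config.noise_sigma > 0:
            noisy = img.pixels.astype(float) + rng.normal(0, self.config.noise_sigma, img.pixels.shape)
            img = RadiographImage(np.clip(np.round(noisy), 0, 255).astype(np.uint8),
                                  img.plane_id, t)
        return img


def _orthogonal_projections(config: SceneConfig) -> tuple[ProjectionModel, ProjectionModel]:
    n = config.image_size
    spacing = config.detector_width / n
    half = (n - 1) / 2.0 * spacing
    # plane A: source anterior (+x), detector behind (-x); u -> +z, v -> -y
    srcA = np.array([config.source_isocenter, 0.0, 0.0])
    # detector origin = pixel (0,0) position: centre - half*(u+v)
    uA, vA = np.array([0.0, 0.0, 1.0]), np.array([0.0, -1.0, 0.0])
    cA = np.array([config.source_isocenter - config.source_detector, 0.0, 0.0])
    originA = cA - half * uA - half * vA
    A = ProjectionModel(srcA, originA, uA, vA, (spacing, spacing), (n, n))
    # plane B: source from the right (+z); u -> -x, v -> -y
    srcB = np.array([0.0, 0.0, config.source_isocenter])
    uB, vB = np.array([-1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0])
    cB = np.array([0.0, 0.0, config.source_isocenter - config.source_detector])
    originB = cB - half * uB - half * vB
    B = ProjectionModel(srcB, originB, uB, vB, (spacing, spacing), (n, n))
    return A, B


def make_scene(config: SceneConfig | None = None, seed: int = 0) -> SyntheticScene:
    """Build a reproducible synthetic knee scene.

    The held-out subject (femur + tibia analogs) is drawn from the shape
    population with weights never used in a training set. The femoral analog
    sits above the isocenter, the tibial analog below, separated by the
    joint gap; the flexion axis is the lab z axis through the isocenter.
    """
    config = config or SceneConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFE]))
    femur = _subject_mesh("femur", config, seed)
    tibia = _subject_mesh("tibia", config, seed)

    fem_vol = voxelize_mesh(femur, spacing=config.voxel_spacing)
    tib_vol = voxelize_mesh(tibia, spacing=config.voxel_spacing)

    # place femur above (+y), tibia below; model frames centred on centroids
    fem_extent = femur.bounds()
    tib_extent = tibia.bounds()
    fem_y = config.joint_gap / 2.0 - fem_extent[0][1]  # bottom at +gap/2
    tib_y = -config.joint_gap / 2.0 - tib_extent[1][1]  # top at -gap/2
    base_poses = {
        "femur": Pose6DOF(0.0, fem_y, 0.0, 0.0, 0.0, 0.0),
        "tibia": Pose6DOF(0.0, tib_y, 0.0, 0.0, 0.0, 0.0),
    }

    markers = rng.uniform(-1, 1, size=(config.n_markers, 3))
    markers = markers / np.linalg.norm(markers, axis=1, keepdims=True)
    markers = markers * rng.uniform(55, 75, size=(config.n_markers, 1))

    return SyntheticScene(
        config=config, seed=seed, femur=femur, tibia=tibia,
        femur_volume=fem_vol, tibia_volume=tib_vol,
        projections=_orthogonal_projections(config),
        marker_positions=markers, base_poses=base_poses,
    )


def _subject_mesh(bone: str, config: SceneConfig, seed: int) -> Mesh:
    _, modes, weights = generate_bone_population(
        n=config.population_n, k=config.population_k, seed=_bone_seed(seed, bone),
        bone=bone, subdivisions=config.subdivisions, extra=1,
    )
    sph = base_bone_mesh(bone, config.subdivisions, size=30.0)
    scale = config.bone_size / 30.0
    v = scale * (sph.vertices.ravel() + modes @ weights[-1])
    return Mesh(v.reshape(-1, 3), sph.faces)


_BONE_IDS = {"femur": 101, "tibia": 202}  # fixed stream ids per bone


def _bone_seed(seed: int, bone: str) -> int:
    return int(np.random.SeedSequence([seed, _BONE_IDS[bone]]).generate_state(1)[0] % (2**31))


def training_population(scene: SyntheticScene, bone: str):
    """The training set matching a scene's held-out subject (same modes)."""
    c = scene.config
    ts, modes, weights = generate_bone_population(
        n=c.population_n, k=c.population_k, seed=_bone_seed(scene.seed, bone),
        bone=bone, subdivisions=c.subdivisions, extra=1,
    )
    if c.bone_size != 30.0:
        s = c.bone_size / 30.0
        ts = TrainingSet([Mesh(m.vertices * s, m.faces) for m in ts.shapes])
    return ts, modes, weights


# ------------------------------------------------------- static acquisitions

@dataclass
class AcquisitionSet:
    """Static multi-view radiograph pairs for shape reconstruction."""

    pairs: list[tuple[RadiographImage, RadiographImage]]
    models: tuple[ProjectionModel, ProjectionModel]
    pair_transforms: list[RigidTransform]  # pair-1 frame -> pair-k frame

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("empty acquisition set")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class InterleavedSequence:
    """Time-stamped alternating-plane frames (A, B, A, B, ...)."""

    frames: list[RadiographImage]
    per_plane_fps: float = 30.0
    offset: float = 1.0 / 60.0

    def __post_init__(self):
        for i, f in enumerate(self.frames):
            if f.plane_id != "AB"[i % 2]:
                raise ValueError("plane ids must strictly alternate A,B,A,B,...")


def simulate_static_acquisitions(
    scene: SyntheticScene,
    bone: str = "femur",
    plate_angles=(0.0, 30.0, 45.0, 60.0),
    marker_jitter_px: float = 0.0,
    seed: int = 0,
    t: float = 0.0,
):
    """Static standing acquisitions at several vertical plate rotations.

    For each angle the whole limb (bone + skin markers) is rotated about the
    vertical (y) axis through the isocenter; both planes are rendered and
    the markers projected (with optional pixel jitter). Returns the
    acquisition set, per-pair per-plane marker observations
    ``(n_pairs, 2, M, 2)`` and the ground-truth pair transforms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xACE]))
    volume = scene.femur_volume if bone == "femur" else scene.tibia_volume
    base_pose = pose_to_transform(scene.bone_pose(bone, t))
    pairs, obs, truth_T = [], [], []
    for angle in plate_angles:
        S = RigidTransform.from_rotvec_deg([0.0, angle, 0.0])
        truth_T.append(S)
        T_bone = S @ base_pose
        imgs = []
        for p, model in enumerate(scene.projections):
            drr = generate_drr(volume, T_bone, model)
            img = drr.to_uint8()
            if scene.config.noise_sigma > 0:
                noisy = img.pixels.astype(float) + rng.normal(
                    0, scene.config.noise_sigma, img.pixels.shape)
                img = RadiographImage(np.clip(np.round(noisy), 0, 255).astype(np.uint8),
                                      "AB"[p], t)
            imgs.append(img)
        pairs.append(tuple(imgs))
        m_world = S.apply(scene.marker_positions)
        per_plane = []
        for model in scene.projections:
            px = model.project_points(m_world)
            if marker_jitter_px > 0:
                px = px + rng.normal(0, marker_jitter_px, px.shape)
            per_plane.append(px)
        obs.append(np.stack(per_plane))
    acq = AcquisitionSet(pairs, scene.projections, truth_T)
    return acq, np.stack(obs), truth_T


# --------------------------------------------------- interleaved sequences

def simulate_interleaved_sequence(
    scene: SyntheticScene,
    duration: float = 2.0,
    per_plane_fps: float = 30.0,
    offset: float = 1.0 / 60.0,
    seed: int = 0,
) -> tuple[InterleavedSequence, dict]:
    """Interleaved bi-plane sequence with per-frame ground truth.

    Frames alternate planes A, B with the inter-unit time offset; each frame
    is rendered at its own timestamp (true asynchrony), 8-bit quantized with
    seeded Gaussian intensity noise. Returns the sequence and a dict with
    per-frame times and truth poses per bone.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E0]))
    dt = 1.0 / per_plane_fps
    times_a = np.arange(0.0, duration, dt)
    frames = []
    times = []
    for ta in times_a:
        for p, t in ((0, ta), (1, ta + offset)):
            frames.append(scene.render_frame(p, t, rng=rng))
            times.append(t)
    truth = {
        "times": np.array(times),
        "femur": [scene.bone_pose("femur", t) for t in times],
        "tibia": [scene.bone_pose("tibia", t) for t in times],
    }
    return InterleavedSequence(frames, per_plane_fps, offset), truth
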