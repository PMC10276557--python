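"""Voxelization and DRR rendering."""

import numpy as np
import pytest

from fluorokin.drr import (AIR_HU, BONE_HU, VoxelVolume, generate_drr,
                           silhouette_region, voxelize_mesh)
from fluorokin.geometry import Pose6DOF, ProjectionModel, RigidTransform
from fluorokin.mesh import Mesh
from fluorokin.synthetic import icosphere


def box_mesh(w, h, d):
    """Axis-aligned box centred at the origin (12 triangles, watertight)."""
    x, y, z = w / 2, h / 2, d / 2
    v = np.array([[sx, sy, sz] for sx in (-x, x) for sy in (-y, y) for sz in (-z, z)])
    f = [[0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5], [0, 4, 5], [0, 5, 1],
         [2, 3, 7], [2, 7, 6], [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3]]
    return Mesh(v, f)


def camera(n=64, spacing=2.0):
    half = (n - 1) / 2 * spacing
    u, v = np.array([0.0, 0.0, 1.0]), np.array([0.0, -1.0, 0.0])
    centre = np.array([-300.0, 0.0, 0.0])
    return ProjectionModel([700.0, 0, 0], centre - half * u - half * v, u, v,
                           (spacing, spacing), (n, n))


class TestVoxelize:
    def test_cube_interior_count(self):
        vol = voxelize_mesh(box_mesh(10, 10, 10), spacing=0.5)
        n_bone = int((vol.values == BONE_HU).sum())
        assert abs(n_bone - 8000) / 8000 < 0.05

    def test_sphere_volume(self):
        s = icosphere(3)
        vol = voxelize_mesh(Mesh(s.vertices * 8.0, s.faces), spacing=0.5)
        est = (vol.values == BONE_HU).sum() * 0.5**3
        analytic = 4 / 3 * np.pi * 8**3
        assert abs(est - analytic) / analytic < 0.02

    def test_default_hu_values(self):
        vol = voxelize_mesh(box_mesh(4, 4, 4), spacing=1.0)
        assert set(np.unique(vol.values)) == {AIR_HU, BONE_HU}

    def test_empty_mesh_raises(self):
        with pytest.raises(ValueError):
            voxelize_mesh(Mesh(np.zeros((0, 3)), np.zeros((0, 3), int)))

    def test_open_mesh_raises_with_edges(self):
        s = icosphere(0)
        broken = Mesh(s.vertices * 5, s.faces[:-1])
        with pytest.raises(ValueError, match="open edges"):
            voxelize_mesh(broken)

    def test_vertices_near_boundary(self, femur_mesh):
        vol = voxelize_mesh(femur_mesh, spacing=1.0)
        # every vertex within one voxel diagonal of an interior/exterior flip
        diag = float(np.linalg.norm(vol.spacing))
        inside = vol.values == BONE_HU
        from scipy.ndimage import binary_dilation

        shell = binary_dilation(inside) & ~inside
        shell_pts = vol.origin + np.argwhere(shell) * vol.spacing
        from scipy.spatial import cKDTree

        d, _ = cKDTree(shell_pts).query(femur_mesh.vertices, k=1)
        assert d.max() < 2 * diag


class TestGenerateDRR:
    def test_all_air_uniform(self):
        vol = VoxelVolume(np.zeros(3), np.ones(3), np.full((8, 8, 8), AIR_HU))
        img = generate_drr(vol, Pose6DOF(), camera())
        assert np.all(img.pixels == 0)

    def test_slab_path_length_linearity(self):
        cam = camera()
        v1 = voxelize_mesh(box_mesh(10, 40, 40), spacing=1.0)
        v2 = voxelize_mesh(box_mesh(20, 40, 40), spacing=1.0)
        c = 31  # central pixel: ray crosses the slab perpendicular to x
        p1 = generate_drr(v1, Pose6DOF(), cam).pixels[c, c]
        p2 = generate_drr(v2, Pose6DOF(), cam).pixels[c, c]
        assert p2 / p1 == pytest.approx(2.0, rel=0.01)
        # absolute value: thickness * (bone - air)
        assert p1 == pytest.approx(10 * (BONE_HU - AIR_HU), rel=0.01)

    def test_single_voxel_projects_at_pinhole_position(self):
        cam = camera()
        values = np.full((5, 5, 5), AIR_HU, dtype=np.float32)
        values[2, 2, 2] = BONE_HU
        centre_world = np.array([3.0, -7.0, 11.0])
        vol = VoxelVolume(centre_world - 2.0, np.ones(3), values)
        img = generate_drr(vol, Pose6DOF(), cam, step=0.25)
        peak = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        expected = cam.project_points(centre_world)
        assert abs(peak[1] - expected[0]) <= 1.0
        assert abs(peak[0] - expected[1]) <= 1.0

    def test_scene_camera_rigid_invariance(self, femur_mesh):
        cam = camera()
        vol = voxelize_mesh(femur_mesh, spacing=1.5)
        pose = Pose6DOF(5, -4, 3, 10, -8, 6)
        ref = generate_drr(vol, pose, cam)
        M = RigidTransform.from_rotvec_deg([12, 25, -18], [20, 10, -15])
        moved_cam = ProjectionModel(M.apply(cam.source), M.apply(cam.detector_origin),
                                    M.rotation @ cam.u_axis, M.rotation @ cam.v_axis,
                                    cam.pixel_spacing, cam.resolution)
        from fluorokin.geometry import pose_to_transform

        moved = generate_drr(vol, M @ pose_to_transform(pose), moved_cam)
        scale = max(ref.pixels.max(), 1.0)
        assert np.abs(moved.pixels - ref.pixels).max() / scale < 1e-5

    def test_region_matches_full_render(self, femur_mesh):
        cam = camera()
        vol = voxelize_mesh(femur_mesh, spacing=1.5)
        pose = Pose6DOF(0, 5, 0)
        full = generate_drr(vol, pose, cam)
        u0, u1, v0, v1 = silhouette_region(vol, pose, cam, dilate=4)
        part = generate_drr(vol, pose, cam, region=(u0, u1, v0, v1))
        assert np.allclose(part.pixels[v0:v1, u0:u1], full.pixels[v0:v1, u0:u1],
                           rtol=1e-6, atol=1e-3)

    def test_brute_force_fine_step_reference(self, femur_mesh):
        """Renderer agrees with an independent fine-step ray-marching oracle."""
        cam = camera(n=32, spacing=4.0)
        vol = voxelize_mesh(femur_mesh, spacing=1.5)
        pose = Pose6DOF(0, 5, 0, 10, 0, 0)
        img = generate_drr(vol, pose, cam)
        from fluorokin.geometry import pose_to_transform

        T = pose_to_transform(pose).inverse()
        step = float(vol.spacing.min()) / 8.0
        shifted = vol.values - np.float32(AIR_HU)
        lo, hi = vol.bounds()
        oracle = np.zeros((32, 32))
        for vpx in range(32):
            for upx in range(32):
                tgt = T.apply(cam.pixel_to_point([upx, vpx]))
                src = T.apply(cam.source)
                d = tgt - src
                d = d / np.linalg.norm(d)
                with np.errstate(divide="ignore"):
                    t1 = (lo - src) / d
                    t2 = (hi - src) / d
                tmin = max(np.minimum(t1, t2).max(), 0.0)
                tmax = np.maximum(t1, t2).min()
                if tmax <= tmin:
                    continue
                ts = np.arange(tmin + step / 2, tmax, step)
                pts = (src + ts[:, None] * d - vol.origin) / vol.spacing
                from scipy.ndimage import map_coordinates

                vals = map_coordinates(shifted, pts.T, order=1, cval=0.0, prefilter=False)
                oracle[vpx, upx] = vals.sum() * step
        scale = max(oracle.max(), 1.0)
        assert np.mean(np.abs(img.pixels - oracle)) / scale < 0.01

    def test_uint8_normalization(self, femur_mesh):
        vol = voxelize_mesh(femur_mesh, spacing=2.0)
        img = generate_drr(vol, Pose6DOF(), camera(), as_uint8=True)
        assert img.pixels.dtype == np.uint8
        assert img.pixels.max() == 255 and img.pixels.min() == 0
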