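"""Gradient correlation, multi-view cost and the genetic-algorithm search."""

import numpy as np
import pytest

from fluorokin.drr import RadiographImage, voxelize_mesh
from fluorokin.geometry import Pose6DOF, RigidTransform
from fluorokin.registration import (SearchSettings, biplane_register,
                                    ga_optimize, gradient_correlation,
                                    multiview_cost)


def brute_force_gc(a, b):
    """Direct-summation oracle: Sobel gradients and both NCC terms written
    out longhand over the interior pixels."""
    a = a.astype(float)
    b = b.astype(float)
    ki = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
    kj = ki.T
    nv, nu = a.shape

    def grad(img, k):
        out = np.zeros((nv - 2, nu - 2))
        for r in range(1, nv - 1):
            for c in range(1, nu - 1):
                acc = 0.0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        acc += img[r + dr, c + dc] * k[1 + dr, 1 + dc]
                out[r - 1, c - 1] = acc
        return out

    total = 0.0
    for k in (ki, kj):
        ga, gb = grad(a, k), grad(b, k)
        da, db = ga - ga.mean(), gb - gb.mean()
        total += (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
    return total


class TestGradientCorrelation:
    def test_self_similarity_is_exactly_two(self, rng):
        img = RadiographImage(rng.random((16, 16)) * 255)
        r = gradient_correlation(img, img)
        assert r.f_gc == 2.0
        assert r.horizontal_term == 1.0 and r.vertical_term == 1.0

    def test_affine_intensity_invariance(self, rng):
        img = rng.random((20, 20)) * 255
        remapped = 3.7 * img + 41.0
        r = gradient_correlation(RadiographImage(img), RadiographImage(remapped))
        assert r.f_gc == pytest.approx(2.0, abs=1e-12)

    def test_symmetry_and_affine_invariance_100_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            a = rng.random((12, 12))
            b = rng.random((12, 12))
            f_ab = gradient_correlation(RadiographImage(a), RadiographImage(b)).f_gc
            f_ba = gradient_correlation(RadiographImage(b), RadiographImage(a)).f_gc
            assert f_ab == pytest.approx(f_ba, abs=1e-12)
            f_scaled = gradient_correlation(
                RadiographImage(2.0 * a + 5), RadiographImage(0.5 * b + 1)).f_gc
            assert f_scaled == pytest.approx(f_ab, abs=1e-10)

    def test_flat_image_raises(self, rng):
        flat = RadiographImage(np.full((10, 10), 7.0))
        tex = RadiographImage(rng.random((10, 10)))
        with pytest.raises(ValueError, match="variance"):
            gradient_correlation(flat, tex)

    def test_mismatched_shapes_raise(self, rng):
        with pytest.raises(ValueError):
            gradient_correlation(RadiographImage(rng.random((8, 8))),
                                 RadiographImage(rng.random((9, 9))))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        got = gradient_correlation(RadiographImage(a), RadiographImage(b)).f_gc
        assert got == pytest.approx(brute_force_gc(a, b), abs=1e-12)


class TestGA:
    def test_sphere_function(self):
        s = SearchSettings(population=60, generations=40, seed=0)
        x, c, hist = ga_optimize(lambda v: float(v @ v), (np.full(6, -10.0), np.full(6, 10.0)), s)
        assert np.abs(x).max() < 1e-2 or c < 1e-3

    def test_constant_cost(self):
        s = SearchSettings(population=10, generations=3, seed=1)
        x, c, _ = ga_optimize(lambda v: 5.0, (np.zeros(2), np.ones(2)), s)
        assert c == 5.0
        assert np.all(x >= 0) and np.all(x <= 1)

    def test_seeded_determinism(self):
        s = SearchSettings(population=20, generations=10, seed=7)
        r1 = ga_optimize(lambda v: float((v - 0.3) @ (v - 0.3)), (np.zeros(4), np.ones(4)), s)
        r2 = ga_optimize(lambda v: float((v - 0.3) @ (v - 0.3)), (np.zeros(4), np.ones(4)), s)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1] and r1[2] == r2[2]

    def test_monotone_elitism(self):
        rng = np.random.default_rng(0)
        s = SearchSettings(population=15, generations=12, seed=3)
        rough = lambda v: float(np.sum(v**2) + 3 * np.sin(5 * v).sum())
        _, c, hist = ga_optimize(rough, (np.full(3, -4.0), np.full(3, 4.0)), s)
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))
        assert c <= hist[0]

    def test_infinite_bounds_raise(self):
        s = SearchSettings(population=5, generations=1, seed=0)
        with pytest.raises(ValueError):
            ga_optimize(lambda v: 0.0, (np.array([-np.inf]), np.array([1.0])), s)


class TestMultiviewCost:
    @pytest.fixture(scope="class")
    def setup(self, scene128):
        scene = scene128
        vol = scene.tibia_volume
        truth = scene.bone_pose("tibia", 0.0)
        imgs = [scene.render_frame(p, 0.0) for p in (0, 1)]  # noiseless, synchronous
        views = [(imgs[p], scene.projections[p], RigidTransform.identity()) for p in (0, 1)]
        return scene, vol, truth, imgs, views

    def test_truth_pose_near_floor(self, scene128):
        # single-bone scene: render DRRs of the tibia volume alone so the
        # cost at the generating pose reaches the -2N floor
        scene = scene128
        from fluorokin.drr import generate_drr

        truth = scene.bone_pose("tibia", 0.0)
        views = []
        for p in (0, 1):
            img = generate_drr(scene.tibia_volume, truth, scene.projections[p])
            views.append((img, scene.projections[p], RigidTransform.identity()))
        cost = multiview_cost(scene.tibia_volume, truth, views)
        assert cost == pytest.approx(-4.0, abs=1e-3)

    def test_single_view_bound(self, setup):
        scene, vol, truth, imgs, views = setup
        c = multiview_cost(vol, truth, views[:1])
        assert -2.0 <= c <= 2.0

    def test_truth_beats_perturbations(self, setup):
        scene, vol, truth, imgs, views = setup
        c0 = multiview_cost(vol, truth, views)
        rng = np.random.default_rng(17)
        for _ in range(20):
            d = rng.uniform(-1, 1, 6)
            d = d / np.abs(d).max() * rng.uniform(1.0, 4.0)  # >= 1 mm / 1 deg
            p = Pose6DOF.from_vector(truth.to_vector() + d)
            assert multiview_cost(vol, p, views) > c0

    def test_empty_views_raise(self, setup):
        scene, vol, truth, imgs, views = setup
        with pytest.raises(ValueError):
            multiview_cost(vol, truth, [])


class TestBiplaneRegister:
    def test_fixed_point_at_truth(self, scene128):
        from fluorokin.drr import generate_drr

        scene = scene128
        truth = scene.bone_pose("tibia", 0.0)
        pair = [(generate_drr(scene.tibia_volume, truth, scene.projections[p]),
                 scene.projections[p]) for p in (0, 1)]
        s = SearchSettings(population=10, generations=4, seed=2)
        est, cost = biplane_register(scene.tibia_volume, truth, pair, s)
        err = est.to_vector() - truth.to_vector()
        assert np.abs(err[:3]).max() < 0.1 and np.abs(err[3:]).max() < 0.1

    def test_recovery_from_offset(self, scene128):
        from fluorokin.drr import generate_drr

        scene = scene128
        truth = scene.bone_pose("tibia", 0.0)
        pair = [(generate_drr(scene.tibia_volume, truth, scene.projections[p]),
                 scene.projections[p]) for p in (0, 1)]
        init = Pose6DOF.from_vector(truth.to_vector() + np.array([2, 2, 2, 2, 2, 2.0]))
        s = SearchSettings(population=30, generations=15, seed=4, polish=True)
        est, _ = biplane_register(scene.tibia_volume, init, pair, s)
        err = est.to_vector() - truth.to_vector()
        assert np.abs(err[:3]).max() < 0.5
        assert np.abs(err[3:]).max() < 0.5

    def test_init_outside_absolute_bounds(self, scene128):
        scene = scene128
        s = SearchSettings(population=5, generations=1, seed=0,
                           absolute_bounds=(np.full(6, -1.0), np.full(6, 1.0)))
        with pytest.raises(ValueError, match="bounds"):
            biplane_register(scene.tibia_volume, Pose6DOF(5, 0, 0),
                             [(scene.render_frame(0, 0.0), scene.projections[0])], s)
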