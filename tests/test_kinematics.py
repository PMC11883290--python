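"""Rigid-body fits, locator attachment and animation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from endocast import (LocatorSet, MarkerSet, RigidTransform,
                      UnderdeterminedError, animate_locators, apply_transform,
                      attach_locators, estimate_rbt, plane_locators)
from endocast.kinematics import rmsd
from endocast.meshvol import TriMesh


def random_rigid(rng) -> RigidTransform:
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return RigidTransform.from_rt(R, rng.normal(scale=5, size=3))


def cube_mesh(side=1.0):
    v = side * (np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float))
    f = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                  [0, 1, 5], [0, 5, 4], [2, 3, 7], [2, 7, 6],
                  [1, 2, 6], [1, 6, 5], [3, 0, 4], [3, 4, 7]])
    return TriMesh(vertices=v, faces=f, name="cube")


class TestEstimateRbt:
    def test_identity_when_observed_equals_reference(self):
        ref = np.random.default_rng(0).normal(size=(5, 3))
        T = estimate_rbt(ref, ref)
        assert np.allclose(T.matrix, np.eye(4), atol=1e-12)
        assert rmsd(T, ref, ref) < 1e-12

    def test_recovers_constructed_motion_exactly(self):
        ref = np.random.default_rng(1).normal(size=(6, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        true = RigidTransform.from_rt(Rz, np.array([1.0, 2.0, 3.0]))
        T = estimate_rbt(ref, true.apply(ref))
        assert np.abs(T.apply(ref) - true.apply(ref)).max() < 1e-10
        assert np.allclose(T.matrix, true.matrix, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_noiseless_recovery_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(rng.integers(3, 9), 3))
        true = random_rigid(rng)
        T = estimate_rbt(ref, true.apply(ref))
        assert np.abs(T.apply(ref) - true.apply(ref)).max() < 1e-9

    def test_coplanar_markers_yield_proper_rotation(self):
        # markers all in a plane: the reflection guard must still produce
        # det(R) = +1
        ref = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
                       dtype=float)
        rng = np.random.default_rng(3)
        true = random_rigid(rng)
        T = estimate_rbt(ref, true.apply(ref))
        assert np.linalg.det(T.R) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(T.apply(ref) - true.apply(ref)).max() < 1e-9

    def test_underdetermined_inputs_rejected(self):
        with pytest.raises(UnderdeterminedError):
            estimate_rbt(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(UnderdeterminedError):
            estimate_rbt(line, line)

    def test_noisy_fit_beats_rotation_grid_oracle(self):
        # Kabsch is the global optimum, so its RMSD can never exceed the
        # best rotation found by a coarse-to-fine grid search (1 deg final
        # resolution) with optimal translation at each grid point.
        rng = np.random.default_rng(42)
        ref = rng.normal(size=(6, 3))
        true = random_rigid(rng)
        obs = true.apply(ref) + rng.normal(scale=0.01, size=(6, 3))
        T = estimate_rbt(ref, obs)

        ref_c = ref - ref.mean(axis=0)
        obs_c = obs - obs.mean(axis=0)

        def grid_rmsd(center, span, n):
            best = (np.inf, None)
            grid = [np.linspace(c - span, c + span, n) for c in center]
            for a in grid[0]:
                for b in grid[1]:
                    for g in grid[2]:
                        R = Rotation.from_euler("zyx", [a, b, g],
                                                degrees=True).as_matrix()
                        d = ref_c @ R.T - obs_c
                        v = np.sqrt(np.mean(np.sum(d**2, axis=1)))
                        if v < best[0]:
                            best = (v, (a, b, g))
            return best

        best = grid_rmsd((0.0, 0.0, 0.0), 180.0, 19)        # 20 deg
        for span in (20.0, 4.0):                            # -> 4, 1 deg
            best = grid_rmsd(best[1], span, 9)
        assert rmsd(T, ref, obs) <= best[0] + 1e-12


class TestApplyTransform:
    def test_identity_and_translation(self):
        pts = np.array([[1.0, 1.0, 1.0]])
        assert np.allclose(apply_transform(RigidTransform.identity(), pts),
                           pts)
        T = RigidTransform.from_rt(np.eye(3), [0, 0, 5])
        assert np.allclose(apply_transform(T, pts), [[1, 1, 6]])

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_distances_preserved(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        T = random_rigid(rng)
        out = T.apply(pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.allclose(d_in, d_out, rtol=1e-9, atol=1e-9)

    def test_composition_matches_sequential_application(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        T1, T2 = random_rigid(rng), random_rigid(rng)
        assert np.allclose((T2 @ T1).apply(pts), T2.apply(T1.apply(pts)),
                           atol=1e-10)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(10)
        T = random_rigid(rng)
        pts = rng.normal(size=(5, 3))
        assert np.allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-10)


class TestAttachLocators:
    def test_all_vertices_with_vertex_subset(self):
        mesh = cube_mesh()
        locs = attach_locators(mesh, 8, strategy="vertex-subset", seed=1)
        assert sorted(map(tuple, locs.local)) == sorted(
            map(tuple, mesh.vertices))

    def test_deterministic_given_seed(self):
        mesh = cube_mesh()
        a = attach_locators(mesh, 5, strategy="farthest-point", seed=7)
        b = attach_locators(mesh, 5, strategy="farthest-point", seed=7)
        assert np.array_equal(a.local, b.local)

    def test_too_many_locators_rejected(self):
        with pytest.raises(ValueError):
            attach_locators(cube_mesh(), 9, strategy="vertex-subset", seed=0)

    def test_farthest_point_spacing_shrinks_with_count(self, noiseless_scene):
        mesh = noiseless_scene.inner_faces["plate_a"]

        def min_pairwise(n):
            pts = attach_locators(mesh, n, strategy="farthest-point",
                                  seed=0).local
            d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            return d[np.triu_indices(n, 1)].min()

        spacing = [min_pairwise(n) for n in (8, 16, 32, 64)]
        assert np.all(np.diff(spacing) <= 1e-12)

    def test_locators_lie_on_surface(self, noiseless_scene):
        mesh = noiseless_scene.inner_faces["plate_b"]
        locs = attach_locators(mesh, 20, seed=3)
        assert np.abs(locs.local[:, 2]).max() < 1e-9  # face is local z=0


class TestPlaneLocators:
    def test_grid_on_z0_plane(self):
        locs = plane_locators([0, 0, 0], [0, 0, 1], ((0, 1), (0, 1)), (3, 3))
        assert len(locs) == 9
        assert np.all(locs.local[:, 2] == 0)
        assert all(p == "midsagittal-plane" for p in locs.parents)

    def test_offset_plane(self):
        locs = plane_locators([0, 2, 0], [0, 1, 0], ((-1, 1), (-1, 1)),
                              (4, 2))
        assert np.allclose(locs.local[:, 1], 2.0)

    def test_rotated_plane_equation_satisfied(self):
        n = np.array([1.0, 2.0, -0.5])
        origin = np.array([0.3, -1.0, 2.0])
        locs = plane_locators(origin, n, ((0, 3), (0, 2)), (5, 4))
        n_hat = n / np.linalg.norm(n)
        assert np.abs((locs.local - origin) @ n_hat).max() < 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            plane_locators([0, 0, 0], [0, 0, 0], ((0, 1), (0, 1)), (2, 2))
        with pytest.raises(ValueError):
            plane_locators([0, 0, 0], [0, 0, 1], ((0, 0), (0, 1)), (2, 2))


class TestAnimateLocators:
    def _locators(self):
        return LocatorSet(ids=("a", "b", "c", "d"),
                          parents=("bone1", "bone1", "plane", "plane"),
                          local=np.array([[0.0, 0, 0], [1, 0, 0],
                                          [0, 1, 0], [0, 0, 1]]))

    def test_identity_transforms_keep_local_coords(self):
        locs = self._locators()
        cloud = animate_locators(
            locs, {"bone1": [RigidTransform.identity()] * 3})
        assert np.allclose(cloud.coords, np.broadcast_to(locs.local, (3, 4, 3)))

    def test_translated_bone_moves_only_its_locators(self):
        locs = self._locators()
        seq = [RigidTransform.from_rt(np.eye(3), [0, 0, f]) for f in range(3)]
        cloud = animate_locators(locs, {"bone1": seq})
        assert np.allclose(cloud.coords[2, 0], [0, 0, 2])
        assert np.allclose(cloud.coords[2, 2], [0, 1, 0])  # static parent

    def test_hinge_rotation_matches_closed_form(self):
        # a locator at local (0, r, 0) rotating about the x-axis
        locs = LocatorSet(ids=("p",), parents=("plate",),
                          local=np.array([[0.0, 2.0, 0.0]]))
        thetas = np.linspace(0, np.pi / 2, 5)
        seq = []
        for th in thetas:
            c, s = np.cos(th), np.sin(th)
            seq.append(RigidTransform.from_rt(
                np.array([[1, 0, 0], [0, c, -s], [0, s, c]]), np.zeros(3)))
        cloud = animate_locators(locs, {"plate": seq})
        expect = np.stack([np.zeros(5), 2 * np.cos(thetas),
                           2 * np.sin(thetas)], axis=1)
        assert np.allclose(cloud.coords[:, 0], expect, atol=1e-12)

    def test_inter_locator_rigidity(self):
        rng = np.random.default_rng(4)
        local = rng.normal(size=(6, 3))
        locs = LocatorSet(ids=tuple("abcdef"), parents=("b",) * 6, local=local)
        seq = [random_rigid(rng) for _ in range(4)]
        cloud = animate_locators(locs, {"b": seq})
        d0 = np.linalg.norm(local[:, None] - local[None], axis=-1)
        for f in range(4):
            df = np.linalg.norm(cloud.coords[f][:, None] -
                                cloud.coords[f][None], axis=-1)
            assert np.allclose(df, d0, rtol=1e-9, atol=1e-9)

    def test_missing_frame_names_bone_and_frame(self):
        locs = self._locators()
        with pytest.raises(ValueError, match="bone1.*frame 1"):
            animate_locators(locs, {"bone1": [RigidTransform.identity(),
                                              None]})


class TestPhantomRoundTrip:
    def test_estimated_rbts_reproduce_true_locator_positions(
            self, noiseless_scene):
        scene = noiseless_scene
        locs = scene.locator_set(24, seed=0)
        true_cloud = scene.frame_cloud(locs, use_estimated_rbt=False)
        est_cloud = scene.frame_cloud(locs, use_estimated_rbt=True)
        assert np.abs(true_cloud.coords - est_cloud.coords).max() < 1e-8

    def test_markerset_collinear_reference_rejected(self):
        line = np.column_stack([np.arange(3.0), np.zeros(3), np.zeros(3)])
        with pytest.raises(UnderdeterminedError):
            MarkerSet(bone="b", reference=line, observed=line[None])
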