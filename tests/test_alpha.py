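"""Alpha-complex geometry: circumradii, retention rule, boundary meshes."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from endocast import (DegenerateCloudError, alpha_complex, boundary_mesh,
                      circumradius, closed_mesh_volume, critical_alpha,
                      tetrahedralize)

from conftest import UNIT_RIGHT_TET, random_cloud, sphere_fit_circumradius


class TestCircumradius:
    def test_regular_tetrahedron_closed_form(self):
        # unit-edge regular tetrahedron: R = sqrt(6)/4
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(8)  # edge length 1
        assert np.allclose(np.linalg.norm(pts[0] - pts[1]), 1.0)
        r = circumradius(pts)
        assert r == pytest.approx(np.sqrt(6) / 4, abs=1e-12)
        assert r == pytest.approx(sphere_fit_circumradius(pts), abs=1e-12)

    def test_unit_right_tetrahedron(self):
        # circumcenter (1/2, 1/2, 1/2), radius sqrt(3)/2
        r = circumradius(UNIT_RIGHT_TET)
        assert r == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_coplanar_points_give_infinity(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
                        dtype=float)
        assert circumradius(flat) == np.inf

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sphere_fit_oracle(self, seed):
        tet = random_cloud(seed, n=4)
        assert circumradius(tet) == pytest.approx(
            sphere_fit_circumradius(tet), rel=1e-9)


class TestTetrahedralize:
    def test_minimal_simplex(self, unit_right_tet):
        ts = tetrahedralize(unit_right_tet)
        assert len(ts) == 1
        assert ts.total_volume == pytest.approx(1 / 6)

    def test_coplanar_cloud_rejected(self):
        flat = np.column_stack([np.arange(8.0) % 3, np.arange(8.0) // 3,
                                np.zeros(8)])
        with pytest.raises(DegenerateCloudError) as exc:
            tetrahedralize(flat)
        assert exc.value.n_points == 8

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateCloudError):
            tetrahedralize(np.zeros((3, 3)))

    @pytest.mark.parametrize("seed", range(4))
    def test_total_volume_equals_convex_hull(self, seed):
        pts = random_cloud(seed, n=30)
        ts = tetrahedralize(pts)
        assert ts.total_volume == pytest.approx(ConvexHull(pts).volume,
                                                rel=1e-12)


class TestAlphaComplex:
    def test_single_simplex_retained(self, unit_right_tet):
        res = alpha_complex(unit_right_tet, alpha=1.0)
        assert res.volume == pytest.approx(1 / 6)
        assert res.n_regions == 1

    def test_alpha_below_circumradius_empty(self, unit_right_tet):
        # circumradius is sqrt(3)/2 ~ 0.866 > 0.5
        res = alpha_complex(unit_right_tet, alpha=0.5)
        assert res.volume == 0.0
        assert res.boundary.n_faces == 0

    def test_large_alpha_recovers_convex_hull(self):
        pts = random_cloud(7, n=40)
        res = alpha_complex(pts, alpha=1e6)
        assert res.volume == pytest.approx(ConvexHull(pts).volume, rel=1e-9)

    def test_degenerate_cloud_warns_and_returns_zero(self):
        flat = np.column_stack([np.arange(6.0), np.arange(6.0) ** 2,
                                np.zeros(6)])
        with pytest.warns(UserWarning, match="degenerate"):
            res = alpha_complex(flat, alpha=1.0)
        assert res.volume == 0.0 and res.degenerate

    def test_invalid_alpha_rejected(self, unit_right_tet):
        with pytest.raises(ValueError):
            alpha_complex(unit_right_tet, alpha=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_volume_monotone_in_alpha(self, seed):
        pts = random_cloud(seed, n=35)
        ts = tetrahedralize(pts)
        radii = ts.circumradii[np.isfinite(ts.circumradii)]
        alphas = np.linspace(0.5 * radii.min(), 1.1 * radii.max(), 25)
        vols = [alpha_complex(ts, a).volume for a in alphas]
        assert np.all(np.diff(vols) >= 0)


class TestCriticalAlpha:
    def test_single_tetrahedron(self, unit_right_tet):
        assert critical_alpha(unit_right_tet) == pytest.approx(
            circumradius(UNIT_RIGHT_TET), abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 11, 29])
    def test_smallest_covering_alpha(self, seed):
        pts = random_cloud(seed, n=30)
        a_star = critical_alpha(pts)
        ts = tetrahedralize(pts)

        def covered(alpha):
            res = alpha_complex(ts, alpha)
            used = np.unique(ts.simplices[res.retained])
            return len(used) == len(pts)

        assert covered(a_star)
        assert not covered(a_star * (1 - 1e-9))

    def test_bounded_by_largest_circumradius(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(40, 3)) * np.array([20.0, 1.0, 1.0])
        ts = tetrahedralize(pts)
        finite = ts.circumradii[np.isfinite(ts.circumradii)]
        assert critical_alpha(ts) <= finite.max()

    def test_degenerate_cloud_raises(self):
        with pytest.raises(DegenerateCloudError):
            critical_alpha(np.zeros((10, 3)))


class TestBoundaryMesh:
    def test_single_tetrahedron_has_four_faces(self, unit_right_tet):
        res = alpha_complex(unit_right_tet, alpha=1.0)
        mesh = boundary_mesh(res)
        assert mesh.n_faces == 4
        assert mesh.is_watertight

    def test_shared_face_cancels(self):
        # two tetrahedra sharing the (0,1,2) face -> 6 boundary faces
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.3, 1.0],
                        [0.3, 0.3, -1.0]])
        res = alpha_complex(pts, alpha=1e6)
        assert len(res.retained) == 2
        assert boundary_mesh(res).n_faces == 6

    @pytest.mark.parametrize("seed", range(3))
    def test_boundary_volume_matches_tetra_sum(self, seed):
        pts = random_cloud(seed, n=45)
        res = alpha_complex(pts, alpha=1e6)
        mesh = res.boundary
        assert mesh.is_watertight
        assert closed_mesh_volume(mesh) == pytest.approx(res.volume, rel=1e-9)

    def test_mid_alpha_boundary_consistent(self):
        pts = random_cloud(13, n=40)
        ts = tetrahedralize(pts)
        mid = np.median(ts.circumradii[np.isfinite(ts.circumradii)])
        res = alpha_complex(ts, float(mid))
        mesh = res.boundary
        assert mesh.is_closed  # every edge in an even number of faces
        assert closed_mesh_volume(mesh) == pytest.approx(res.volume, rel=1e-9)
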