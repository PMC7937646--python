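"""Eye-model and projective-geometry unit tests."""

import numpy as np
import pytest

from retinastats import (
    CAT_EYE,
    HUMAN_EYE,
    VisualFieldCoord,
    homography_for,
    plane_point,
    sphere_point,
    tangent_approx_error,
    tangent_plane_at,
)
from retinastats.geometry import pixel_pitch_mm


def grid_coords(n_phi=25, n_chi=40, phi_max=60.0):
    phis = np.linspace(0.0, phi_max, n_phi)
    chis = np.linspace(0.0, 360.0, n_chi, endpoint=False)
    return [VisualFieldCoord(p, c) for p in phis for c in chis]


class TestEyeModel:
    def test_radius_is_half_focal_length(self):
        assert HUMAN_EYE.radius_mm == pytest.approx(16.67 / 2)
        assert CAT_EYE.radius_mm == pytest.approx(12.5 / 2)

    def test_sphere_center_behind_origin(self):
        c = HUMAN_EYE.sphere_center_mm
        assert c[0] == c[1] == 0.0
        assert c[2] == pytest.approx(-HUMAN_EYE.radius_mm)


class TestVisualFieldCoord:
    def test_chi_wraps_mod_360(self):
        assert VisualFieldCoord(30, 405).polar_angle_deg == pytest.approx(45)
        assert VisualFieldCoord(30, -45).polar_angle_deg == pytest.approx(315)

    def test_center_is_degenerate_in_chi(self):
        assert VisualFieldCoord(0.0, 123.0).polar_angle_deg == 0.0
        assert VisualFieldCoord(0.0) == VisualFieldCoord(0.0, 270.0)

    def test_eccentricity_range_enforced(self):
        with pytest.raises(ValueError):
            VisualFieldCoord(90.0)
        with pytest.raises(ValueError):
            VisualFieldCoord(-1.0)


class TestSpherePoint:
    def test_sphere_membership_1000_points(self):
        # Spec-level oracle: every sphere point lies on the retinal sphere to
        # 1e-9 * r over a 1,000-point grid.
        eye = HUMAN_EYE
        coords = grid_coords()
        assert len(coords) == 1000
        pts = np.array([sphere_point(c, eye) for c in coords])
        d = np.linalg.norm(pts - eye.sphere_center_mm, axis=1)
        assert np.max(np.abs(d - eye.radius_mm)) < 1e-9 * eye.radius_mm

    def test_on_ray_through_plane_point(self):
        eye = CAT_EYE
        for c in (VisualFieldCoord(10, 33), VisualFieldCoord(50, 200)):
            s, p = sphere_point(c, eye), plane_point(c, eye)
            assert np.linalg.norm(np.cross(s, p)) < 1e-9 * np.linalg.norm(p) ** 2

    def test_center_maps_to_back_pole(self):
        s = sphere_point(VisualFieldCoord(0.0), HUMAN_EYE)
        np.testing.assert_allclose(s, [0, 0, -2 * HUMAN_EYE.radius_mm], atol=1e-12)


class TestPlanePoint:
    def test_plane_depth_and_tangent_relation(self):
        eye = HUMAN_EYE
        f = 2 * eye.radius_mm
        c = VisualFieldCoord(30, 45)
        p = plane_point(c, eye)
        assert p[2] == pytest.approx(-f)
        assert np.hypot(p[0], p[1]) == pytest.approx(f * np.tan(np.radians(30)))


class TestTangentPlane:
    def test_normal_angle_is_twice_eccentricity(self):
        eye = HUMAN_EYE
        for phi in (0.0, 15.0, 30.0, 44.0):
            tp = tangent_plane_at(VisualFieldCoord(phi, 120.0), eye)
            cosang = -tp.normal[2]  # angle against -z
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == pytest.approx(
                2 * phi, abs=1e-9
            )

    def test_basis_orthonormal_and_tangent(self):
        tp = tangent_plane_at(VisualFieldCoord(40, 10), CAT_EYE)
        G = tp.basis @ tp.basis.T
        np.testing.assert_allclose(G, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(tp.basis @ tp.normal, [0, 0], atol=1e-12)

    def test_points_lie_on_plane(self):
        tp = tangent_plane_at(VisualFieldCoord(25, 300), HUMAN_EYE)
        pts = tp.points(np.array([1.0, -2.0]), np.array([0.5, 3.0]))
        offs = pts - tp.tangent_point_mm
        np.testing.assert_allclose(offs @ tp.normal, 0.0, atol=1e-12)


class TestHomography:
    def test_identity_at_center(self):
        h = homography_for(VisualFieldCoord(0.0), HUMAN_EYE, 0.01)
        np.testing.assert_allclose(h.matrix, np.eye(3), atol=1e-12)

    def test_maps_patch_center_to_origin(self):
        h = homography_for(VisualFieldCoord(30, 45), HUMAN_EYE, 0.0097)
        np.testing.assert_allclose(h.apply(np.zeros(2)), np.zeros(2), atol=1e-9)

    def test_inverse_round_trip(self):
        h = homography_for(VisualFieldCoord(50, 135), HUMAN_EYE, 0.0097)
        xy = np.array([[3.0, -7.0], [60.0, 40.0], [-20.0, 5.0]])
        hom = np.concatenate([h.apply(xy), np.ones((3, 1))], axis=1)
        back = hom @ h.inverse_matrix.T
        np.testing.assert_allclose(back[:, :2] / back[:, 2:], xy, atol=1e-9)

    def test_corresponding_points_share_ray(self):
        # A tangent pixel and its planar preimage must be collinear with the
        # center of projection (the defining property of the homography).
        eye = HUMAN_EYE
        coord = VisualFieldCoord(35, 200)
        pitch = pixel_pitch_mm(eye, 5954, 120.0)
        h = homography_for(coord, eye, pitch)
        tp = tangent_plane_at(coord, eye)
        p_plane = plane_point(coord, eye)
        rng = np.random.default_rng(0)
        for q in rng.uniform(-50, 50, (20, 2)):
            qt = h.apply(q)
            pt3 = tp.points(qt[0] * pitch, qt[1] * pitch)
            pp3 = p_plane + np.array([q[0] * pitch, q[1] * pitch, 0.0])
            cr = np.cross(pt3, pp3)
            assert np.linalg.norm(cr) < 1e-6 * np.linalg.norm(pp3) ** 2


class TestTangentApproxError:
    def test_center_error_matches_sagitta(self):
        # At the back pole the plane-to-sphere gap is the spherical sagitta
        # rho^2 / (2r) at the patch corner.
        eye = HUMAN_EYE
        pitch = pixel_pitch_mm(eye, 5954, 120.0)
        rho = np.hypot(63.5 * pitch, 63.5 * pitch)
        expected = rho**2 / (2 * eye.radius_mm)
        got = tangent_approx_error(VisualFieldCoord(0.0), eye)
        assert got == pytest.approx(expected, rel=0.02)

    def test_grows_with_eccentricity(self):
        errs = [
            tangent_approx_error(VisualFieldCoord(p, 0), HUMAN_EYE)
            for p in (0, 10, 30, 50)
        ]
        assert errs[0] < errs[1] < errs[2] < errs[3]

    def test_grows_with_patch_size(self):
        e128 = tangent_approx_error(VisualFieldCoord(30, 0), HUMAN_EYE, patch_px=128)
        e256 = tangent_approx_error(VisualFieldCoord(30, 0), HUMAN_EYE, patch_px=256)
        assert e256 > e128

    def test_perpendicular_pairing_bounds_ray(self):
        # The perpendicular distance to the sphere is the minimal pairing, so
        # it can only be smaller than the along-ray distance.
        c = VisualFieldCoord(30, 0)
        er = tangent_approx_error(c, HUMAN_EYE, pairing="ray")
        ep = tangent_approx_error(c, HUMAN_EYE, pairing="perpendicular")
        assert 0 < ep <= er
        assert ep > 0.5 * er  # same order of magnitude

    def test_unknown_pairing_raises(self):
        with pytest.raises(ValueError):
            tangent_approx_error(VisualFieldCoord(30, 0), HUMAN_EYE, pairing="x")
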