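"""3D proptosis measurement: landmarks, distances, composition."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage, optimize

import orbitometry as om
from orbitometry.labelmap import Mask
from orbitometry.proptometry import (ProptometryError, SearchRegion,
                                     exterior_surface_voxels, hull_depths)

H = 0.5


def _sphere_mask(center, radius, n=60, h=H):
    return om.ball_mask((n, n, n), (h, h, h), center, radius)


def _notched_shell(notches, center=(15.0, 15.0, 15.0), radius=9.0, n=60, h=H):
    """Solid sphere with hemispherical notches machined at unit directions."""
    c = np.asarray(center)
    xs = np.arange(n) * h
    X, Y, Z = xs[:, None, None], xs[None, :, None], xs[None, None, :]
    m = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius ** 2
    for u, r_notch in notches:
        u = np.asarray(u, dtype=float)
        u = u / np.linalg.norm(u)
        nc = c + radius * u
        m &= ((X - nc[0]) ** 2 + (Y - nc[1]) ** 2 + (Z - nc[2]) ** 2) > r_notch ** 2
    return Mask(m, (h, h, h))


class TestProptosisDistance:
    def test_symmetric_geometry(self):
        assert om.proptosis_distance((0, 20, 0), (-50, 0, 0), (50, 0, 0)) == \
            pytest.approx(20.0)

    def test_apex_on_line_is_zero(self):
        assert om.proptosis_distance((0, 0, 0), (-50, 0, 0), (50, 0, 0)) == \
            pytest.approx(0.0)

    def test_tilted_line_hand_value(self):
        # |100*25 - 10*50| / sqrt(100^2 + 10^2)
        d = om.proptosis_distance((0, 25, 0), (-50, 0, 0), (50, 10, 0))
        assert d == pytest.approx(2000.0 / math.sqrt(10100.0), abs=1e-9)
        assert d == pytest.approx(19.90, abs=0.005)

    def test_coincident_bases_rejected(self):
        with pytest.raises(ProptometryError):
            om.proptosis_distance((0, 1, 0), (3, 3, 3), (3, 3, 3))

    def test_signed_convention_flags_posterior_apex(self):
        signed = om.proptosis_distance((0, -5, 0), (-50, 0, 0), (50, 0, 0),
                                       signed=True)
        assert signed == pytest.approx(-5.0)

    @given(apex=st.tuples(*[st.floats(-40, 40)] * 3),
           b1=st.tuples(*[st.floats(-60, -10)] * 1, *[st.floats(-20, 20)] * 2),
           b2=st.tuples(*[st.floats(10, 60)] * 1, *[st.floats(-20, 20)] * 2),
           convention=st.sampled_from(["in_plane", "full_3d"]))
    def test_matches_brute_force_line_minimization(self, apex, b1, b2, convention):
        a = np.asarray(apex, dtype=float)
        p1 = np.asarray(b1, dtype=float)
        p2 = np.asarray(b2, dtype=float)
        if convention == "in_plane":
            a, p1, p2 = (np.array([v[0], v[1], 0.0]) for v in (a, p1, p2))

        def dist(t):
            return np.linalg.norm(a - (p1 + t * (p2 - p1)))

        res = optimize.minimize_scalar(dist, bounds=(-50, 50), method="bounded",
                                       options={"xatol": 1e-12})
        got = om.proptosis_distance(apex, b1, b2, convention)
        assert got == pytest.approx(res.fun, abs=1e-6)


class TestApexSlice:
    def test_sphere_equator(self):
        m = _sphere_mask((15.0, 15.0, 15.0), 9.0)
        assert abs(om.find_apex_slice(m) - 30) <= 1

    def test_translation_equivariance(self):
        m1 = _sphere_mask((15.0, 15.0, 12.0), 8.0)
        m2 = Mask(np.roll(m1.data, 5, axis=2), m1.spacing, m1.origin)
        assert om.find_apex_slice(m2) == om.find_apex_slice(m1) + 5

    def test_prolate_ellipsoid_equatorial_slice(self):
        n, h = 60, H
        xs = np.arange(n) * h
        X, Y, Z = xs[:, None, None], xs[None, :, None], xs[None, None, :]
        m = ((X - 15) ** 2 / 7 ** 2 + (Y - 15) ** 2 / 12 ** 2
             + (Z - 15) ** 2 / 7 ** 2) <= 1.0
        assert abs(om.find_apex_slice(Mask(m, (h, h, h))) - 30) <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ProptometryError):
            om.find_apex_slice(Mask(np.zeros((4, 4, 4), bool), (1, 1, 1)))


class TestCornealApex:
    def test_sphere_apex_at_anterior_pole(self):
        c, r = (15.0, 15.0, 15.0), 9.0
        m = _sphere_mask(c, r)
        apex = om.corneal_apex(m, om.find_apex_slice(m))
        np.testing.assert_allclose(apex, (15.0, 24.0, 15.0), atol=H * math.sqrt(3))

    def test_anterior_translation_moves_apex(self):
        m1 = _sphere_mask((15.0, 12.0, 15.0), 8.0)
        m2 = _sphere_mask((15.0, 16.0, 15.0), 8.0)
        a1 = om.corneal_apex(m1, om.find_apex_slice(m1))
        a2 = om.corneal_apex(m2, om.find_apex_slice(m2))
        assert a2[1] - a1[1] == pytest.approx(4.0, abs=H)

    def test_flat_face_tie_breaks_to_centroid(self):
        data = np.zeros((40, 40, 9), dtype=bool)
        data[4:30, 5:20, :] = True  # flat anterior face, wide in x
        m = Mask(data, (H, H, H))
        apex = om.corneal_apex(m, 4)
        centroid_x = np.argwhere(data)[:, 0].mean() * H
        assert apex[0] == pytest.approx(centroid_x, abs=H)
        assert apex[1] == pytest.approx(19 * H)


class TestBasePoint:
    def test_phantom_notch_recovered_within_one_voxel(self, default_phantom):
        spec, pre, _, truth = default_phantom
        bone = pre.organ_mask(om.BONE)
        mid = spec.midline_x
        center = (spec.axis_x, 30.0, spec.orbit_axis_z)
        for side in ("left", "right"):
            region = SearchRegion.upper_outer(center, side, mid)
            bp = om.detect_base_point(bone, side, region)
            err = np.linalg.norm(bp.point - np.asarray(truth.base_points[side]))
            assert err <= math.sqrt(3) * H

    def test_convex_shell_has_no_concavity(self):
        m = _sphere_mask((15.0, 15.0, 15.0), 9.0)
        region = SearchRegion(z_above=15.0, x_beyond=0.0, outward=1)
        with pytest.raises(om.DegenerateSurfaceError):
            om.detect_base_point(m, "right", region)

    def test_deeper_of_two_notches_wins(self):
        u_deep = (0.6, 0.3, 0.75)
        u_shallow = (0.75, -0.3, 0.6)
        m = _notched_shell([(u_deep, 4.0), (u_shallow, 2.0)])
        region = SearchRegion(z_above=13.0, x_beyond=15.0, outward=1)
        bp = om.detect_base_point(m, "right", region)
        c = np.array([15.0, 15.0, 15.0])
        deep_bottom = c + 5.0 * np.asarray(u_deep) / np.linalg.norm(u_deep)
        shallow_bottom = c + 7.0 * np.asarray(u_shallow) / np.linalg.norm(u_shallow)
        assert np.linalg.norm(bp.point - deep_bottom) < \
            np.linalg.norm(bp.point - shallow_bottom)
        assert np.linalg.norm(bp.point - deep_bottom) < 2.0

    def test_agrees_with_exhaustive_depth_search(self):
        m = _notched_shell([((0.6, 0.3, 0.75), 4.0)])
        region = SearchRegion(z_above=13.0, x_beyond=15.0, outward=1)
        bp = om.detect_base_point(m, "right", region)

        # independent exhaustive search: loop over every admitted surface
        # voxel and every hull facet one by one
        from scipy.spatial import ConvexHull
        idx = np.argwhere(exterior_surface_voxels(m.data))
        pts = m.world_points(idx)
        pts = pts[region.admits(pts)]
        depths = hull_depths(pts)
        hull = ConvexHull(pts)
        brute = []
        for p in pts:
            d = min(-(eq[:3] @ p + eq[3]) for eq in hull.equations)
            brute.append(max(d, 0.0))
        np.testing.assert_allclose(depths, brute, atol=1e-9)
        assert bp.depth == pytest.approx(float(depths.max()), abs=1e-12)
        plateau_tol = 0.5 * math.sqrt(3) * H
        plateau = pts[depths >= depths.max() - plateau_tol]
        assert any(np.allclose(bp.point, p) for p in plateau)


class TestMeasureProptosis:
    def test_phantom_distance_matches_analytic(self, default_phantom):
        _, pre, _, truth = default_phantom
        res = om.measure_proptosis(pre)
        assert res.distance == pytest.approx(truth.proptosis_distance_pre,
                                             abs=math.sqrt(3) * H)
        assert not res.posterior_to_line

    def test_translation_invariance(self, default_phantom):
        _, pre, _, _ = default_phantom
        shifted = dataclasses.replace(pre, origin=(37.0, -11.0, 240.0))
        d0 = om.measure_proptosis(pre).distance
        d1 = om.measure_proptosis(shifted).distance
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_globe_advance_increases_distance(self):
        base = om.PhantomSpec(boundary_noise=0.0)
        fwd = om.PhantomSpec(boundary_noise=0.0, globe_center_y=38.0)
        d_base = om.measure_proptosis(om.generate_phantom(base, 0)[0]).distance
        d_fwd = om.measure_proptosis(om.generate_phantom(fwd, 0)[0]).distance
        assert d_base - d_fwd == pytest.approx(3.0, abs=H)

    def test_programmed_retraction_recovered(self, default_phantom):
        _, pre, post, truth = default_phantom
        r_pre = om.measure_proptosis(pre, orbit_id="p")
        r_post = om.measure_proptosis(post, orbit_id="p", timepoint="post")
        red = om.proptosis_reduction(r_pre, r_post)
        assert red.reduction == pytest.approx(truth.proptosis_reduction, abs=H)

    def test_rotation_robustness(self, default_phantom):
        _, pre, _, _ = default_phantom
        d0 = om.measure_proptosis(pre).distance
        rot = ndimage.rotate(pre.data, 5.0, axes=(0, 1), reshape=False, order=0)
        d5 = om.measure_proptosis(pre.with_data(rot)).distance
        assert abs(d5 - d0) <= 2 * H


class TestReduction:
    def _result(self, distance, timepoint="pre", convention="in_plane"):
        return om.ProptosisResult(
            orbit_id="p", timepoint=timepoint, left_base=(20, 33, 33),
            right_base=(119, 33, 33), corneal_apex=(52, 52, 28), apex_slice=56,
            distance=distance, convention=convention)

    def test_subtraction(self):
        red = om.proptosis_reduction(self._result(21.0),
                                     self._result(17.8, "post"))
        assert red.reduction == pytest.approx(3.2)

    def test_no_change_is_zero(self):
        red = om.proptosis_reduction(self._result(18.0),
                                     self._result(18.0, "post"))
        assert red.reduction == 0.0

    def test_convention_mismatch_rejected(self):
        with pytest.raises(ProptometryError):
            om.proptosis_reduction(self._result(21.0),
                                   self._result(17.8, "post", "full_3d"))
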