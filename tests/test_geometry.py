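import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jawkit import geometry as geo
from jawkit.errors import DegenerateGeometry, NearIdentityRotation
from jawkit.geometry import Line3, Plane, RigidTransform


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


class TestPlaneFromPoints:
    def test_axis_aligned(self):
        p = geo.plane_from_points([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert np.allclose(p.normal, [0, 0, 1])
        assert p.offset == pytest.approx(0.0)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometry):
            geo.plane_from_points([0, 0, 0], [1, 0, 0], [2, 0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cross_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(-50, 50, (3, 3))
        plane = geo.plane_from_points(a, b, c)
        n_oracle = np.cross(b - a, c - a)
        n_oracle /= np.linalg.norm(n_oracle)
        assert np.allclose(plane.normal, n_oracle, atol=1e-12)
        for p in (a, b, c):
            assert abs(geo.signed_distance(p, plane)) < 1e-9


class TestSignedDistance:
    def test_point_on_plane_is_zero(self):
        p = geo.plane_from_points([0, 0, 0], [1, 0, 0], [0, 1, 0])
        assert geo.signed_distance([2.5, -3.0, 0.0], p) == pytest.approx(0.0)

    def test_axis_aligned_sign(self):
        p = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        assert geo.signed_distance([5, 5, 3], p) == pytest.approx(3.0)
        assert geo.signed_distance([5, 5, -3], p) == pytest.approx(-3.0)

    def test_matches_grid_minimization_oracle(self):
        rng = np.random.default_rng(3)
        plane = geo.plane_from_points(*rng.uniform(-20, 20, (3, 3)))
        point = rng.uniform(-20, 20, 3)
        # dense grid of plane points around the orthogonal projection
        foot = geo.project_point(point, plane)
        e1 = np.cross(plane.normal, [1.0, 0.3, -0.2])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(plane.normal, e1)
        g = np.linspace(-2, 2, 201)
        pts = foot + g[:, None, None] * e1 + g[None, :, None] * e2
        oracle = np.min(np.linalg.norm(pts.reshape(-1, 3) - point, axis=1))
        assert abs(geo.signed_distance(point, plane)) == pytest.approx(oracle, abs=1e-6)


class TestAngleLinePlane:
    @pytest.mark.parametrize("direction,expected", [
        ([1, 0, 0], 0.0),
        ([0, 0, 1], 90.0),
        (np.array([1, 0, 1]) / np.sqrt(2), 45.0),
    ])
    def test_against_fh_like_plane(self, direction, expected):
        plane = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
        line = Line3(np.zeros(3), np.asarray(direction, dtype=float))
        assert geo.angle_line_plane(line, plane) == pytest.approx(expected, abs=1e-9)


class TestFitLine:
    def test_exact_line_zero_residual(self):
        t = np.linspace(-5, 5, 20)
        d = np.array([2.0, -1.0, 0.5])
        d /= np.linalg.norm(d)
        pts = np.array([3.0, 1.0, -2.0]) + np.outer(t, d)
        fit = geo.fit_line(pts)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)
        assert abs(np.dot(fit.line.direction, d)) == pytest.approx(1.0, abs=1e-12)

    def test_mirrored_clouds_give_mirror_axis(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(0, 0.4, (30, 3)) + np.array([0.0, 2.0, 1.0])
        cloud[:, 0] += rng.uniform(-10, 10, 30)
        pts = np.vstack([cloud, cloud * [1, -1, -1]])  # reflect through the x-axis
        fit = geo.fit_line(pts)
        # the symmetry axis is x: the fitted direction must be +-x exactly
        assert abs(fit.line.direction[0]) > 1 - 1e-12
        assert np.allclose(fit.line.point[1:], 0.0, atol=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateGeometry):
            geo.fit_line(np.zeros((2, 3)))

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometry):
            geo.fit_line(np.ones((5, 3)))

    @pytest.mark.parametrize("seed", range(3))
    def test_beats_random_candidate_lines(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1, (25, 3)) * np.array([4.0, 1.0, 0.5])
        fit = geo.fit_line(pts)
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        for _ in range(1000):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            perp = centered - np.outer(centered @ d, d)
            rms = np.sqrt(np.mean(np.sum(perp ** 2, axis=1)))
            assert fit.rms_residual <= rms + 1e-12


class TestRigidTransform:
    def test_identity_recovered(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [3, 4, 5.0]])
        T = geo.estimate_rigid_transform(pts, pts)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-12)

    def test_collinear_reference_raises(self):
        ref = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(DegenerateGeometry):
            geo.estimate_rigid_transform(ref, ref)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_recovers_any_proper_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.uniform(-50, 50, (5, 3))
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, 3)
        T = geo.estimate_rigid_transform(ref, ref @ R.T + t)
        assert np.max(np.abs(T.rotation - R)) < 1e-9
        assert np.max(np.abs(T.translation - t)) < 1e-9

    def test_batch_matches_single(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(-50, 50, (4, 3))
        stack = np.array([ref @ random_rotation(rng).T + rng.uniform(-5, 5, 3)
                          for _ in range(6)])
        Rb, tb = geo.batch_rigid_transforms(ref, stack)
        for i in range(6):
            T = geo.estimate_rigid_transform(ref, stack[i])
            assert np.allclose(Rb[i], T.rotation, atol=1e-10)
            assert np.allclose(tb[i], T.translation, atol=1e-10)


class TestScrewAxis:
    def test_pure_z_rotation(self):
        ang = np.radians(30)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        sa = geo.screw_axis(RigidTransform(R, np.zeros(3)))
        assert np.allclose(np.abs(sa.axis.direction), [0, 0, 1])
        assert sa.angle_deg == pytest.approx(30.0, abs=1e-9)
        assert sa.pitch_mm == pytest.approx(0.0, abs=1e-12)

    def test_identity_raises(self):
        with pytest.raises(NearIdentityRotation):
            geo.screw_axis(RigidTransform.identity())

    @pytest.mark.parametrize("seed", range(4))
    def test_recovers_offset_axis(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        p0 = rng.uniform(-30, 30, 3)
        ang = rng.uniform(5, 90)
        c, s = np.cos(np.radians(ang)), np.sin(np.radians(ang))
        K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * K @ K
        t = p0 - R @ p0  # rotation about the line through p0
        sa = geo.screw_axis(RigidTransform(R, t))
        assert sa.angle_deg == pytest.approx(ang, abs=1e-6)
        assert np.degrees(np.arccos(min(1.0, abs(sa.axis.direction @ d)))) < 1e-6
        # axis passes through p0: perpendicular distance ~ 0
        off = p0 - sa.axis.point
        perp = off - (off @ sa.axis.direction) * sa.axis.direction
        assert np.linalg.norm(perp) < 1e-6

    def test_composition_doubles_angle_same_axis(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ang = np.radians(41.0)
        K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
        p0 = np.array([5.0, -3.0, 7.0])
        T = RigidTransform(R, p0 - R @ p0)
        sa1 = geo.screw_axis(T)
        sa2 = geo.screw_axis(T.compose(T))
        assert sa2.angle_deg == pytest.approx(2 * sa1.angle_deg, abs=1e-9)
        assert abs(sa1.axis.direction @ sa2.axis.direction) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(sa1.axis.point, sa2.axis.point, atol=1e-6)
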