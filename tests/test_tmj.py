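import numpy as np
import pytest

from conftest import mirror_landmarks
from jawkit import cranio, synth, tmj
from jawkit.errors import DegenerateGeometry, ProfileGapError
from jawkit.geometry import RigidTransform


def identity_frame():
    lm, _ = synth.generate_skull(synth.SkullConfig(), seed=0)
    return cranio.build_head_frame(lm)  # identity CHS for an unmoved skull


def circle_outline(cx, cy, r, z, n=64):
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th),
                            np.full(n, z)])


class TestCondyleCenter:
    def test_circle_center(self):
        frame = identity_frame()
        geom = tmj.CondyleGeometry("left", [3 - 10, 4, -8], [3 + 10, 4, -8],
                                   circle_outline(3, 4, 10, -8), [3, 4, 0])
        cc = tmj.condyle_center(geom, frame)
        assert np.allclose(cc, [3, 4, -8], atol=1e-9)

    def test_irregular_convex_matches_vertex_pair_oracle(self):
        frame = identity_frame()
        rng = np.random.default_rng(4)
        th = np.sort(rng.uniform(0, 2 * np.pi, 24))
        r = 8 + rng.uniform(-1.5, 1.5, 24)
        out = np.column_stack([50 + r * np.cos(th), 30 + r * np.sin(th),
                               np.full(24, -8.0)])
        med, lat = out[3], out[15]
        geom = tmj.CondyleGeometry("left", med, lat, out, [50, 30, 0])
        cc = tmj.condyle_center(geom, frame)
        # oracle: exhaustive vertex-pair chords of maximal extent along the
        # pole direction and its in-plane perpendicular
        u = (lat - med)[:2]
        u /= np.linalg.norm(u)
        v = np.array([-u[1], u[0]])
        xy = out[:, :2]

        def best_pair(direction):
            pairs = [(i, j) for i in range(24) for j in range(24)]
            return max(pairs, key=lambda ij: abs((xy[ij[0]] - xy[ij[1]]) @ direction))

        i1, j1 = best_pair(u)
        i2, j2 = best_pair(v)
        d1 = xy[j1] - xy[i1]
        d2 = xy[j2] - xy[i2]
        A = np.column_stack([d1, -d2])
        s = np.linalg.solve(A, xy[i2] - xy[i1])
        expected = xy[i1] + s[0] * d1
        assert np.allclose(cc[:2], expected, atol=1e-9)

    def test_coincident_poles_raise(self):
        frame = identity_frame()
        geom = tmj.CondyleGeometry("left", [0, 0, -8], [0, 0, -8],
                                   circle_outline(0, 0, 10, -8), [0, 0, 0])
        with pytest.raises(DegenerateGeometry):
            tmj.condyle_center(geom, frame)


class TestCondylarPosture:
    def test_coordinate_readoff(self):
        frame = identity_frame()
        apcp, tcp, vcp = tmj.condylar_posture(np.array([13.0, 52.0, -8.7]), frame)
        assert (apcp, tcp, vcp) == pytest.approx((13.0, 52.0, 8.7))

    def test_on_midsagittal_plane(self):
        frame = identity_frame()
        assert tmj.condylar_posture(np.array([13.0, 0.0, -8.7]), frame)[1] == 0.0


def sphere_fossa_case(shift_y=0.0):
    """Spherical condyle (r=8) under a concentric spherical fossa (R=10) at
    left-condyle position; all joint spaces are 2 mm (closed form)."""
    c = np.array([13.0, 52.0 + shift_y, -8.0])
    fc = np.array([13.0, 52.0, -8.0])  # fossa center stays put
    out = circle_outline(c[0], c[1], 8.0, c[2], n=128)
    geom = tmj.CondyleGeometry("left", c + [0, -8, 0], c + [0, 8, 0], out,
                               c + [0, 0, 8])
    th = np.linspace(-0.6, 0.6, 181)
    walls = {}
    for wall, (sx, sy) in (("anterior", (1, 0)), ("posterior", (-1, 0)),
                           ("medial", (0, -1)), ("lateral", (0, 1))):
        if sx:
            pts = np.column_stack([fc[0] + sx * 10 * np.cos(th),
                                   np.full_like(th, fc[1]),
                                   fc[2] + 10 * np.sin(th)])
        else:
            pts = np.column_stack([np.full_like(th, fc[0]),
                                   fc[1] + sy * 10 * np.cos(th),
                                   fc[2] + 10 * np.sin(th)])
        walls[wall] = pts
    roof = fc + np.array([0.0, 0.0, 10.0])
    fossa = tmj.FossaGeometry("left", roof, walls)
    return geom, fossa


class TestJointSpaces:
    def test_concentric_sphere_closed_form(self):
        frame = identity_frame()
        geom, fossa = sphere_fossa_case()
        sjs, ajs, pjs, mjs, ljs = tmj.joint_spaces(geom, fossa, frame)
        assert (sjs, ajs, pjs, mjs, ljs) == pytest.approx((2.0,) * 5, abs=2e-3)

    def test_medial_shift_closed_form(self):
        frame = identity_frame()
        geom, fossa = sphere_fossa_case(shift_y=-1.0)  # 1 mm medially (left side)
        sjs, ajs, pjs, mjs, ljs = tmj.joint_spaces(geom, fossa, frame)
        assert mjs == pytest.approx(1.0, abs=2e-3)
        assert ljs == pytest.approx(3.0, abs=2e-3)
        assert sjs == pytest.approx(2.0, abs=1e-9)

    def test_profile_gap_detected(self):
        frame = identity_frame()
        geom, fossa = sphere_fossa_case()
        # anterior wall arc slid far upward: nearest point becomes an end
        # point well off the anterior measurement direction
        fossa.wall_profiles["anterior"] = fossa.wall_profiles["anterior"] + \
            np.array([0.0, 0.0, 14.0])
        with pytest.raises(ProfileGapError):
            tmj.joint_spaces(geom, fossa, frame)

    def test_small_translation_changes_opposing_spaces_linearly(self):
        frame = identity_frame()
        base = tmj.joint_spaces(*sphere_fossa_case(), frame)
        d = 0.05
        shifted = tmj.joint_spaces(*sphere_fossa_case(shift_y=-d), frame)
        assert shifted[3] == pytest.approx(base[3] - d, abs=1e-3)
        assert shifted[4] == pytest.approx(base[4] + d, abs=1e-3)


class TestAxialCondylarAngle:
    def test_pure_mediolateral_poles(self):
        frame = identity_frame()
        geom = tmj.CondyleGeometry("left", [13, 42, -8], [13, 62, -8],
                                   circle_outline(13, 52, 10, -8), [13, 52, 0])
        mag, _ = tmj.axial_condylar_angle(geom, frame)
        assert mag == pytest.approx(0.0, abs=1e-9)

    def test_45_degree_pole_line(self):
        frame = identity_frame()
        geom = tmj.CondyleGeometry("left", [13 - 7, 52 - 7, -8], [13 + 7, 52 + 7, -8],
                                   circle_outline(13, 52, 10, -8), [13, 52, 0])
        mag, sign = tmj.axial_condylar_angle(geom, frame)
        assert mag == pytest.approx(45.0, abs=1e-9)
        assert sign == 1  # medial pole posterior


class TestEminenceSteepness:
    def test_generator_round_trip(self, default_subject, measured_default):
        _, _, truth = default_subject
        tr = measured_default["tmj"]
        for side in ("left", "right"):
            for k, v in tr.side_values(side).items():
                assert v == pytest.approx(truth[f"{k}_{side}"], abs=1e-6), (k, side)

    def test_horizontal_profile_zero(self):
        lm, _ = synth.generate_skull(synth.SkullConfig(), seed=0)
        frame = cranio.build_head_frame(lm)
        fossa = tmj.fossa_from_landmarks(lm, "left")
        x = np.linspace(10, 22, 9)
        fossa.wall_profiles["anterior"] = np.column_stack(
            [x, np.full(9, 52.0), np.full(9, 4.0)])
        aes, *_ = tmj.eminence_steepness(fossa, frame)
        assert aes == pytest.approx(0.0, abs=1e-9)

    def test_vertical_wall_rejected(self):
        frame = identity_frame()
        geom, fossa = sphere_fossa_case()
        z = np.linspace(-4, 8, 9)
        fossa.wall_profiles["anterior"] = np.column_stack(
            [np.full(9, 21.0), np.full(9, 52.0), z])
        with pytest.raises(DegenerateGeometry):
            tmj.eminence_steepness(fossa, frame)


class TestRecordLevelProperties:
    def test_mirror_swaps_side_blocks(self, default_subject):
        lm, _, _ = default_subject
        tr = tmj.tmj_record(lm, cranio.build_head_frame(lm))
        mlm = mirror_landmarks(lm)
        mtr = tmj.tmj_record(mlm, cranio.build_head_frame(mlm))
        for a, b in (("left", "right"), ("right", "left")):
            for k, v in tr.side_values(a).items():
                assert mtr.side_values(b)[k] == pytest.approx(v, abs=1e-9), k

    def test_rigid_world_motion_invariance(self):
        cfg = synth.SkullConfig()
        lm0, _ = synth.generate_skull(cfg, seed=0, world_pose="identity")
        tr0 = tmj.tmj_record(lm0, cranio.build_head_frame(lm0))
        lm1, _ = synth.generate_skull(cfg, seed=5, world_pose="random")
        tr1 = tmj.tmj_record(lm1, cranio.build_head_frame(lm1))
        for side in ("left", "right"):
            for k, v in tr0.side_values(side).items():
                assert tr1.side_values(side)[k] == pytest.approx(v, abs=1e-8), k
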