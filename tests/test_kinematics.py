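import numpy as np
import pytest

from jawkit import cranio, kinematics as kin, synth, tmj
from jawkit.errors import (DegeneratePath, MissingMovement, NoRotationPhase,
                           PathTooShort, SchemaError)
from jawkit.geometry import Line3


def make_recording(markers, incisor, movement="open_close", fps=30.0):
    n = markers.shape[0]
    return kin.MotionRecording(movement, np.arange(n) / fps, markers, incisor)


def rotate_about(axis_point, axis_dir, angle, pts):
    d = axis_dir / np.linalg.norm(axis_dir)
    K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
    return (pts - axis_point) @ R.T + axis_point


class TestHingeAxisEstimation:
    def test_pure_rotation_recovers_axis_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-40, 40, (4, 3))
        inc = np.array([90.0, 0.0, -45.0])
        p0 = np.array([10.0, 0.0, -5.0])
        d = np.array([0.05, 1.0, 0.02])
        d /= np.linalg.norm(d)
        angles = np.radians(np.linspace(0, 9, 40))
        markers = np.array([rotate_about(p0, d, a, base) for a in angles])
        incisor = np.array([rotate_about(p0, d, a, inc) for a in angles])
        hinge = kin.estimate_hinge_axis(make_recording(markers, incisor))
        assert abs(hinge.hinge_axis.direction @ d) > 1 - 1e-12
        off = p0 - hinge.hinge_axis.point
        perp = off - (off @ d) * d
        assert np.linalg.norm(perp) < 1e-6

    def test_pure_translation_raises(self):
        base = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [5, 5, 8.0]])
        shifts = np.linspace(0, 10, 30)
        markers = np.array([base + [s, 0, 0] for s in shifts])
        incisor = np.tile([90.0, 0, -45], (30, 1))
        with pytest.raises(NoRotationPhase):
            kin.estimate_hinge_axis(make_recording(markers, incisor))

    def test_noisy_recovery_within_spec(self):
        # median direction error < 0.5 deg and reference-point error < 0.3 mm
        # at 0.05 mm marker noise
        cfg = synth.SkullConfig()
        lm, _ = synth.generate_skull(cfg, seed=1)
        frame = cranio.build_head_frame(lm)
        cc = tmj.condylar_centers(lm.transformed(frame.to_chs),
                                  cranio.build_head_frame(lm.transformed(frame.to_chs)))
        true_d = cc["left"] - cc["right"]
        true_d /= np.linalg.norm(true_d)
        dir_errs, ref_errs = [], []
        for seed in range(15):
            mcfg = synth.MotionConfig(marker_noise_sd=0.05)
            rec, _ = synth.generate_motion(lm, mcfg, "open_close", seed=seed)
            hinge = kin.estimate_hinge_axis(rec, condylar_centers=cc)
            dir_errs.append(np.degrees(np.arccos(
                min(1.0, abs(hinge.hinge_axis.direction @ true_d)))))
            ref_errs.append(np.linalg.norm(
                hinge.condylar_reference_points["left"] - cc["left"]))
        assert np.median(dir_errs) < 0.5
        assert np.median(ref_errs) < 0.3


class TestPaths:
    def test_identity_frames_give_single_points(self):
        base = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [5, 5, 8.0]])
        markers = np.tile(base, (25, 1, 1))
        incisor = np.tile([90.0, 0, -45], (25, 1))
        rec = make_recording(markers, incisor, movement="protrusion")
        hinge = kin.hinge_frame_from_axis(
            Line3(np.array([10.0, 0, -5]), np.array([0.0, 1.0, 0.0])),
            {"left": np.array([10.0, 52, -5]), "right": np.array([10.0, -52, -5])})
        paths = kin.condylar_paths(rec, hinge)
        for p in paths.values():
            assert kin.path_length(p) == 0.0

    def test_round_trip_against_generator_truth(self, default_subject, measured_default):
        _, _, truth = default_subject
        kr = measured_default["kin"]
        for side in ("left", "right"):
            for k, v in kr.side_values(side).items():
                assert v == pytest.approx(truth[f"{k}_{side}"], abs=1e-6), (k, side)


class TestPathLength:
    def test_single_point(self):
        assert kin.path_length(np.zeros((1, 3))) == 0.0

    def test_straight_segment(self):
        t = np.linspace(0, 1, 50)[:, None]
        path = t * np.array([9.18, 0, 0])
        assert kin.path_length(path) == pytest.approx(9.18, abs=1e-12)

    def test_semicircle_arc_length(self):
        r = 7.0
        th = np.linspace(0, np.pi, 1000)
        path = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros_like(th)])
        assert kin.path_length(path) == pytest.approx(np.pi * r, rel=1e-3)

    def test_monotone_under_extension_and_rigid_invariance(self):
        rng = np.random.default_rng(1)
        steps = rng.uniform(0, 0.5, (40, 3))
        steps[:, 0] = np.abs(steps[:, 0]) + 0.5  # drifting leg
        path = np.cumsum(steps, axis=0)
        lens = [kin.path_length(path[:k]) for k in range(2, 41)]
        assert np.all(np.diff(lens) >= -1e-12)
        from test_geometry import random_rotation
        R = random_rotation(rng)
        assert kin.path_length(path @ R.T + 5.0) == pytest.approx(
            kin.path_length(path), abs=1e-9)


class TestInclinations:
    def test_sagittal_45(self):
        t = np.linspace(0, 6, 30)[:, None]
        path = t * np.array([np.cos(np.radians(45)), 0, -np.sin(np.radians(45))])
        sci, tci = kin.condylar_inclinations(path, "left")
        assert sci == pytest.approx(45.0, abs=1e-9)
        assert tci == pytest.approx(0.0, abs=1e-9)

    def test_axial_10_deg_medial(self):
        # left condyle: medial = -y
        t = np.linspace(0, 6, 30)[:, None]
        path = t * np.array([np.cos(np.radians(10)), -np.sin(np.radians(10)), 0])
        sci, tci = kin.condylar_inclinations(path, "left")
        assert sci == pytest.approx(0.0, abs=1e-9)
        assert tci == pytest.approx(10.0, abs=1e-9)
        # the same trajectory is lateral for a right condyle
        _, tci_r = kin.condylar_inclinations(path, "right")
        assert tci_r == pytest.approx(-10.0, abs=1e-9)

    def test_short_path_raises(self):
        path = np.linspace(0, 0.5, 25)[:, None] * np.array([1.0, 0, 0])
        with pytest.raises(DegeneratePath):
            kin.condylar_inclinations(path, "left")


class TestBennettAngle:
    def test_straight_anteromedial(self):
        t = np.linspace(0, 5, 40)[:, None]
        path = t * np.array([np.cos(np.radians(15)), np.sin(np.radians(15)), 0])
        assert kin.bennett_angle(path) == pytest.approx(15.0, abs=1e-9)

    def test_straight_anterior_zero(self):
        path = np.linspace(0, 5, 40)[:, None] * np.array([1.0, 0, 0])
        assert kin.bennett_angle(path) == pytest.approx(0.0, abs=1e-9)

    def test_too_short_raises(self):
        path = np.linspace(0, 0.8, 30)[:, None] * np.array([1.0, 0, 0])
        with pytest.raises(PathTooShort):
            kin.bennett_angle(path)

    def test_turning_path_matches_resampling_oracle(self):
        # straight for 0.5 mm, then a 25-degree axial turn
        d1 = np.array([1.0, 0.0, 0.0])
        d2 = np.array([np.cos(np.radians(25)), np.sin(np.radians(25)), 0.0])
        knots = np.vstack([np.zeros(3), 0.5 * d1, 0.5 * d1 + 3.0 * d2])
        t1 = np.linspace(0, 1, 8)[:, None]
        path = np.vstack([knots[0] + t1 * (knots[1] - knots[0]),
                          (knots[1] + t1 * (knots[2] - knots[1]))[1:]])
        got = kin.bennett_angle(path)
        # oracle: dense resampling of the same polyline at 1e-5 mm steps
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        cum = np.concatenate([[0], np.cumsum(seg)])
        s = np.arange(0, cum[-1], 1e-5)
        dense = np.column_stack([np.interp(s, cum, path[:, i]) for i in range(3)])
        idx = int(np.searchsorted(s, 1.0))
        chord = dense[idx] - dense[0]
        expected = abs(np.degrees(np.arctan2(chord[1], chord[0])))
        assert got == pytest.approx(expected, abs=1e-3)

    def test_mirror_flips_tci_and_preserves_ba(self):
        rng = np.random.default_rng(2)
        path = np.cumsum(np.abs(rng.uniform(0, 0.4, (30, 3))) *
                         np.array([1.0, 0.3, -0.2]), axis=0)
        mirrored = path * np.array([1.0, -1.0, 1.0])
        assert kin.bennett_angle(mirrored) == pytest.approx(
            kin.bennett_angle(path), abs=1e-12)
        _, tci = kin.condylar_inclinations(path, "left")
        _, tci_m = kin.condylar_inclinations(mirrored, "right")
        assert tci_m == pytest.approx(tci, abs=1e-12)


class TestKinematicRecord:
    def test_missing_movement_raises(self, default_subject, measured_default):
        _, recs, _ = default_subject
        partial = {k: v for k, v in recs.items() if k != "protrusion"}
        with pytest.raises(MissingMovement):
            kin.kinematic_record(partial, measured_default["hinge"])

    def test_recording_schema_validation(self):
        with pytest.raises(SchemaError):
            kin.MotionRecording("sideways", np.arange(25) / 30.0,
                               np.zeros((25, 4, 3)), np.zeros((25, 3)))
        with pytest.raises(SchemaError):  # too few frames
            kin.MotionRecording("protrusion", np.arange(10) / 30.0,
                               np.random.default_rng(0).normal(size=(10, 4, 3)),
                               np.zeros((10, 3)))
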