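"""Synthetic subjects: stylized asymmetric skulls and rigid-body jaw-motion
recordings with sensor noise, carrying full ground truth.

The skull template is a stylized landmark/polyline model, not an anatomical
mesh: the measurement modules depend only on named landmarks and wall
profiles, so the generator places those primitives such that measuring the
generated subject at zero noise returns the configured parameter values
exactly.  Motion recordings are generated from rigid-body kinematics — a
terminal hinge rotation followed by eminence-guided gliding for opening,
straight condylar translation for protrusion, and a pivoting excursion for
laterotrusion — plus i.i.d. isotropic Gaussian marker noise.

Rigid-body coupling.  A rigid mandible cannot realize two *arbitrary*
independent straight condylar trajectories: once one condylar path and the
other side's descent angle are prescribed, the contralateral extent traces a
conic section determined by the fixed intercondylar distance.  The generator
prescribes the larger-extent condylar path exactly and solves the small free
azimuth of the contralateral direction so that extent is exact as well; the
contralateral transverse inclination is then a derived quantity (the azimuth
the solve lands on — the long intercondylar lever absorbs most of the
in-plane mismatch, so it usually stays near the request).  Ground truth is
always the parameter value computed from the analytic noiseless trajectories
with the same parameter definitions the measurement stage uses.

Cohort generation draws per-subject parameter values from per-side Gaussians
(deviated side vs non-deviated side) with a configurable pairing correlation,
plus a shared latent factor on the deviated side that induces the observed
morpho-functional correlation pattern (ramal inclination, anterior eminence
steepness, medial joint space, axial condylar angle and protrusive path
length co-vary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .cranio import LandmarkSet, SIDES
from .errors import InvalidConfig
from .geometry import Line3, RigidTransform
from .kinematics import (MOVEMENTS, MotionRecording, bennett_angle,
                         condylar_inclinations, hinge_frame_from_axis, path_length)

_SIGN = {"left": 1.0, "right": -1.0}


# ---------------------------------------------------------------------------
# configuration containers


@dataclass(frozen=True)
class PerSide:
    left: float
    right: float

    def __getitem__(self, side: str) -> float:
        return getattr(self, side)

    def as_dict(self) -> dict[str, float]:
        return {"left": self.left, "right": self.right}


@dataclass
class SkullConfig:
    """Ground-truth morphometric parameters of one synthetic subject.

    Defaults place the deviated side on the left with interside differences of
    the magnitude reported for mandibular-asymmetry cohorts.  Lengths in mm,
    angles in degrees.
    """

    menton_deviation: float = 4.5          # signed, + = toward the left
    maxillary_height: PerSide = PerSide(49.67, 50.45)
    ramal_height: PerSide = PerSide(45.91, 48.40)
    frontal_ramal_inclination: PerSide = PerSide(82.34, 77.00)
    lateral_ramal_inclination: PerSide = PerSide(86.41, 83.93)
    body_length: PerSide = PerSide(74.62, 75.58)
    posture_ap: PerSide = PerSide(13.21, 13.80)
    posture_transverse: PerSide = PerSide(52.03, 52.77)
    posture_vertical: PerSide = PerSide(8.72, 8.29)
    joint_space_superior: PerSide = PerSide(2.05, 2.26)
    joint_space_anterior: PerSide = PerSide(2.13, 1.74)
    joint_space_posterior: PerSide = PerSide(1.59, 2.01)
    joint_space_medial: PerSide = PerSide(2.65, 1.60)
    joint_space_lateral: PerSide = PerSide(1.48, 1.77)
    axial_condylar_angle: PerSide = PerSide(21.18, 17.23)
    eminence_anterior: PerSide = PerSide(46.49, 39.10)
    eminence_posterior: PerSide = PerSide(58.30, 58.84)
    eminence_medial: PerSide = PerSide(48.72, 49.10)
    eminence_lateral: PerSide = PerSide(37.77, 39.62)
    anb: float = -2.5
    pog_nperp: float = 2.0

    def validate(self) -> None:
        pos = ["maxillary_height", "ramal_height", "body_length", "posture_ap",
               "posture_transverse", "posture_vertical", "joint_space_superior",
               "joint_space_anterior", "joint_space_posterior",
               "joint_space_medial", "joint_space_lateral"]
        for name in pos:
            ps = getattr(self, name)
            if ps.left <= 0 or ps.right <= 0:
                raise InvalidConfig(f"{name} must be positive")
        for name in ["eminence_anterior", "eminence_posterior",
                     "eminence_medial", "eminence_lateral"]:
            ps = getattr(self, name)
            if not (0 < ps.left < 89 and 0 < ps.right < 89):
                raise InvalidConfig(f"{name} must lie in (0, 89) degrees")
        for name in ["frontal_ramal_inclination", "lateral_ramal_inclination"]:
            ps = getattr(self, name)
            if not (0 < ps.left < 180 and 0 < ps.right < 180):
                raise InvalidConfig(f"{name} must lie in (0, 180) degrees")
        if not (0 < self.axial_condylar_angle.left < 89
                and 0 < self.axial_condylar_angle.right < 89):
            raise InvalidConfig("axial_condylar_angle must lie in (0, 89) degrees")


@dataclass
class MotionConfig:
    """Requested dynamic parameters and recording settings.

    ``opening_slope_deg`` is the sagittal descent angle of the condylar glide
    during opening; ``lateral_descent_deg`` the descent of the non-working
    condyle during laterotrusion.  ``hinge_phase_deg`` is the pure-rotation
    (terminal hinge) segment at the start of opening; the estimator is never
    told where it ends.
    """

    ocpl: PerSide = PerSide(15.27, 14.21)
    pcpl: PerSide = PerSide(9.18, 6.88)
    sci: PerSide = PerSide(44.39, 39.57)
    tci: PerSide = PerSide(4.20, -2.44)
    ncpl: PerSide = PerSide(8.15, 6.12)
    bennett: PerSide = PerSide(14.39, 9.11)
    nipl: PerSide = PerSide(6.59, 5.81)
    opening_slope_deg: float = 50.0
    lateral_descent_deg: float = 25.0
    max_opening_rotation_deg: float = 32.0
    hinge_phase_deg: float = 10.0
    frame_rate: float = 30.0
    opening_duration_s: float = 2.5
    excursion_duration_s: float = 1.5
    marker_noise_sd: float = 0.0

    def validate(self) -> None:
        for name in ["ocpl", "pcpl", "ncpl", "nipl"]:
            ps = getattr(self, name)
            if ps.left <= 0 or ps.right <= 0:
                raise InvalidConfig(f"{name} must be positive")
        if self.marker_noise_sd < 0:
            raise InvalidConfig("marker_noise_sd must be >= 0")
        if self.frame_rate <= 0:
            raise InvalidConfig("frame_rate must be positive")
        if not 0 < self.hinge_phase_deg < self.max_opening_rotation_deg:
            raise InvalidConfig("hinge phase must be a proper prefix of the opening rotation")


# ---------------------------------------------------------------------------
# skull generation


def _ellipse_outline(center_xy, w, a, b, z, n=32):
    """Axial ellipse polyline with vertices on both principal axes."""
    th = 2.0 * np.pi * np.arange(n) / n
    wp = np.array([-w[1], w[0]])
    xy = center_xy[None, :] + np.outer(a * np.cos(th), w) + np.outer(b * np.sin(th), wp)
    return np.column_stack([xy, np.full(n, z)])


def _wall_profile_2d(foot_2d, dir_2d, half_len=6.0, n=7):
    u = np.linspace(-half_len, half_len, n)
    return foot_2d[None, :] + np.outer(u, dir_2d)


def generate_skull(config: SkullConfig, seed: int = 0,
                   world_pose: str | RigidTransform = "identity"
                   ) -> tuple[LandmarkSet, dict[str, float]]:
    """Construct a landmark set realizing ``config`` exactly, plus ground truth.

    The skull is first laid out in canonical head coordinates (FH = {z = 0},
    MSR = {y = 0}, coronal = {x = 0}) and then optionally moved by a random or
    given world pose, which the measurement stage must undo.
    """
    config.validate()
    dev = config.menton_deviation
    pts: dict[str, np.ndarray] = {
        "Ba": np.array([0.0, 0.0, -15.0]),
        "Na": np.array([95.0, 0.0, 5.0]),
        "PoR": np.array([10.0, -55.0, 0.0]),
        "PoL": np.array([10.0, 55.0, 0.0]),
        "OrL": np.array([80.0, 28.0, 0.0]),
        "Me": np.array([94.0, dev, -64.0]),
    }
    # sagittal points encoding ANB and Pog-NPerp
    na = pts["Na"]
    a_pt = np.array([96.0, 0.0, -20.0])
    ang_a = np.arctan2(a_pt[0] - na[0], na[2] - a_pt[2])
    ang_b = ang_a - np.radians(config.anb)
    zb = -48.0
    pts["A"] = a_pt
    pts["B"] = np.array([na[0] + (na[2] - zb) * np.tan(ang_b), 0.0, zb])
    pts["Pog"] = np.array([na[0] + config.pog_nperp, 0.0, -58.0])

    profiles: dict[tuple[str, str], np.ndarray] = {}
    for side in SIDES:
        sgn = _SIGN[side]
        mxh = config.maxillary_height[side]
        pts["U6" + _sfx(side)] = np.array([60.0, sgn * 25.0, -mxh])

        cc = np.array([config.posture_ap[side], sgn * config.posture_transverse[side],
                       -config.posture_vertical[side]])
        co = cc + np.array([0.0, 0.0, 8.0])  # condylar dome height 8 mm
        pts["Co" + _sfx(side)] = co

        # gonion: on the body-length circle around menton (axial), dropped to
        # the sphere of ramal height around the condylar highest point
        bl = config.body_length[side]
        phi = np.radians(35.0)
        go_xy = pts["Me"][:2] + bl * np.array([-np.cos(phi), sgn * np.sin(phi)])
        d_ax = np.linalg.norm(go_xy - co[:2])
        rh = config.ramal_height[side]
        if rh <= d_ax + 1.0:
            raise InvalidConfig(
                f"ramal height {rh:.1f} mm too short for the configured body "
                f"geometry (axial gonion-condyle distance {d_ax:.1f} mm)")
        go = np.array([go_xy[0], go_xy[1], co[2] - np.sqrt(rh * rh - d_ax * d_ax)])
        pts["Go" + _sfx(side)] = go

        # ramus border pairs encoding the frontal/lateral inclinations
        fri = np.radians(config.frontal_ramal_inclination[side])
        pts["RamusLatInf" + _sfx(side)] = go
        pts["RamusLatSup" + _sfx(side)] = go + np.array(
            [-18.0, sgn * 40.0 * np.cos(fri), 40.0 * np.sin(fri)])
        lri = np.radians(config.lateral_ramal_inclination[side])
        prb_inf = go + np.array([-3.0, sgn * 2.0, 0.0])
        pts["RamusPostInf" + _sfx(side)] = prb_inf
        pts["RamusPostSup" + _sfx(side)] = prb_inf + np.array(
            [38.0 * np.cos(lri), sgn * 1.0, 38.0 * np.sin(lri)])

        # condylar outline (axial ellipse at pole level) and poles
        psi = np.radians(config.axial_condylar_angle[side])
        w = np.array([np.sin(psi), sgn * np.cos(psi)])  # medial -> lateral, medial pole posterior
        a_ml, b_ap = 10.0, 7.0
        outline = _ellipse_outline(cc[:2], w, a_ml, b_ap, cc[2])
        profiles[(side, "condyle_outline")] = outline
        pts["CondPoleMed" + _sfx(side)] = np.array([*(cc[:2] - a_ml * w), cc[2]])
        pts["CondPoleLat" + _sfx(side)] = np.array([*(cc[:2] + a_ml * w), cc[2]])

        # fossa roof (superior joint space) and the four wall profiles
        pts["FossaRoof" + _sfx(side)] = co + np.array(
            [1.0, sgn * 0.5, config.joint_space_superior[side]])
        prom = {
            "anterior": outline[int(np.argmax(outline[:, 0]))],
            "posterior": outline[int(np.argmin(outline[:, 0]))],
            "medial": outline[int(np.argmin(sgn * outline[:, 1]))],
            "lateral": outline[int(np.argmax(sgn * outline[:, 1]))],
        }
        spaces = {"anterior": config.joint_space_anterior[side],
                  "posterior": config.joint_space_posterior[side],
                  "medial": config.joint_space_medial[side],
                  "lateral": config.joint_space_lateral[side]}
        slopes = {"anterior": config.eminence_anterior[side],
                  "posterior": config.eminence_posterior[side],
                  "medial": config.eminence_medial[side],
                  "lateral": config.eminence_lateral[side]}
        for wall in ("anterior", "posterior"):
            ang = np.radians(slopes[wall])
            d2 = np.array([np.cos(ang), np.sin(ang)])      # sagittal (x, z)
            n2 = np.array([np.sin(ang), -np.cos(ang)])     # unit normal, +x side
            if wall == "posterior":
                n2 = -n2
            foot = prom[wall][[0, 2]] + spaces[wall] * n2
            prof2 = _wall_profile_2d(foot, d2)
            profiles[(side, f"fossa_{wall}")] = np.column_stack(
                [prof2[:, 0], np.full(prof2.shape[0], cc[1]), prof2[:, 1]])
        for wall in ("medial", "lateral"):
            ang = np.radians(slopes[wall])
            d2 = np.array([np.cos(ang), np.sin(ang)])      # coronal (y, z)
            n2 = np.array([np.sin(ang), -np.cos(ang)])
            want = -sgn if wall == "medial" else sgn       # y-sign of the wall side
            if np.sign(n2[0]) != np.sign(want):
                n2 = -n2
            foot = prom[wall][[1, 2]] + spaces[wall] * n2
            prof2 = _wall_profile_2d(foot, d2)
            profiles[(side, f"fossa_{wall}")] = np.column_stack(
                [np.full(prof2.shape[0], cc[0]), prof2[:, 0], prof2[:, 1]])

    # mandibular tracker markers and the incisal point (rigid with the mandible)
    pts["Marker1"] = np.array([20.0, 50.0, -35.0])
    pts["Marker2"] = np.array([20.0, -50.0, -35.0])
    pts["Marker3"] = np.array([90.0, 25.0, -48.0])
    pts["Marker4"] = np.array([90.0, -25.0, -48.0])
    pts["LowerIncisor"] = np.array([96.0, 0.5 * dev, -45.0])

    lm = LandmarkSet(pts, profiles)
    truth = ground_truth_from_config(config)
    pose = _resolve_pose(world_pose, seed)
    if pose is not None:
        lm = lm.transformed(pose)
    return lm, truth


def _sfx(side: str) -> str:
    return "_L" if side == "left" else "_R"


def _resolve_pose(world_pose, seed) -> RigidTransform | None:
    if isinstance(world_pose, RigidTransform):
        return world_pose
    if world_pose == "identity":
        return None
    if world_pose == "random":
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-50.0, 50.0, 3)
        return RigidTransform(R, t)
    raise InvalidConfig(f"unknown world_pose {world_pose!r}")


_CONFIG_KEYS = {
    "MxH": "maxillary_height", "RH": "ramal_height",
    "FRI": "frontal_ramal_inclination", "LRI": "lateral_ramal_inclination",
    "BL": "body_length", "APCP": "posture_ap", "TCP": "posture_transverse",
    "VCP": "posture_vertical", "SJS": "joint_space_superior",
    "AJS": "joint_space_anterior", "PJS": "joint_space_posterior",
    "MJS": "joint_space_medial", "LJS": "joint_space_lateral",
    "ACA": "axial_condylar_angle", "AES": "eminence_anterior",
    "PES": "eminence_posterior", "MES": "eminence_medial",
    "LES": "eminence_lateral",
}


def ground_truth_from_config(config: SkullConfig) -> dict[str, float]:
    truth = {"menton_deviation": config.menton_deviation,
             "ANB": config.anb, "PogNPerp": config.pog_nperp}
    for var, attr in _CONFIG_KEYS.items():
        ps = getattr(config, attr)
        for side in SIDES:
            truth[f"{var}_{side}"] = ps[side]
    return truth


# ---------------------------------------------------------------------------
# motion generation


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _coupled_extent(delta0, u_a, u_b, a_vals, r0):
    """Contralateral extents b(t) keeping |delta0 + a u_a - b u_b| = r0.

    Root branch is followed by continuity from b = 0 at a = 0.
    """
    P = delta0[None, :] + np.outer(a_vals, u_a)
    c = P @ u_b
    disc = c * c - np.einsum("ni,ni->n", P, P) + r0 * r0
    if np.any(disc < 0):
        raise InvalidConfig("requested condylar trajectories are not rigidly compatible")
    sq = np.sqrt(disc)
    b = np.empty_like(a_vals)
    prev = 0.0
    for i in range(a_vals.shape[0]):
        r1, r2 = c[i] - sq[i], c[i] + sq[i]
        prev = r1 if abs(r1 - prev) <= abs(r2 - prev) else r2
        b[i] = prev
    return b


def _poses_from_condyles(A0, B0, pl, pr, spin_rad):
    """Rigid poses carrying the resting condylar points onto the prescribed
    trajectories, with an additional spin about the moving intercondylar axis.

    Returns stacked rotation matrices (n, 3, 3) and translations (n, 3).
    """
    d0 = (B0 - A0) / np.linalg.norm(B0 - A0)
    dt = pr - pl
    dt = dt / np.linalg.norm(dt, axis=1, keepdims=True)
    # minimal rotations d0 -> dt
    c = np.cross(np.broadcast_to(d0, dt.shape), dt)
    s = np.linalg.norm(c, axis=1)
    dot = dt @ d0
    ang = np.arctan2(s, dot)
    safe = np.where(s > 1e-12, s, 1.0)
    rotvec = c / safe[:, None] * ang[:, None]
    rotvec[s <= 1e-12] = 0.0
    R1 = Rotation.from_rotvec(rotvec).as_matrix()
    Rs = Rotation.from_rotvec(dt * np.asarray(spin_rad)[:, None]).as_matrix()
    R = Rs @ R1
    t = pl - np.einsum("nij,j->ni", R, A0)
    return R, t


@dataclass
class _MandibleContext:
    """Resting mandible geometry needed to synthesize recordings."""

    cc: dict[str, np.ndarray]       # condylar centers, CHS
    markers: np.ndarray             # (4, 3)
    incisor: np.ndarray             # (3,)

    @staticmethod
    def from_landmarks(lm: LandmarkSet) -> "_MandibleContext":
        from .cranio import build_head_frame
        from .tmj import condylar_centers
        frame = build_head_frame(lm)
        chs = lm.transformed(frame.to_chs)
        cc = condylar_centers(chs, build_head_frame(chs))
        markers = np.array([chs.get(f"Marker{i}") for i in range(1, 5)])
        return _MandibleContext(cc, markers, chs.get("LowerIncisor"))


def _true_hinge_frame(ctx: _MandibleContext):
    d = ctx.cc["left"] - ctx.cc["right"]
    axis = Line3(ctx.cc["right"], d / np.linalg.norm(d))
    return hinge_frame_from_axis(axis, dict(ctx.cc))


def _half_profile(n_half, mcfg: MotionConfig, movement: str):
    f = np.linspace(0.0, 1.0, n_half)
    if movement == "open_close":
        # the terminal-hinge rotation is performed slowly (40 % of the opening
        # time) before the glide carries the rest of the rotation
        f1 = 0.4
        theta_hinge = np.radians(mcfg.hinge_phase_deg)
        theta_rest = np.radians(mcfg.max_opening_rotation_deg) - theta_hinge
        theta = np.where(f < f1, theta_hinge * f / f1,
                         theta_hinge + theta_rest * (f - f1) / (1.0 - f1))
        glide = _smoothstep((f - f1) / (1.0 - f1))
        return theta, glide
    return np.zeros(n_half), _smoothstep(f)


def _mirror(arr, n_hold: int = 0):
    """Out leg, an optional hold at the maximum, then the return leg (the
    hold emulates the instructed pause at maximum excursion)."""
    hold = np.full(n_hold, arr[-1])
    return np.concatenate([arr, hold, arr[-2::-1]])


def generate_motion(skull: LandmarkSet, mconfig: MotionConfig, movement: str,
                    seed: int = 0) -> tuple[MotionRecording, dict[str, float]]:
    """One movement recording for a synthetic subject, plus the true values of
    the dynamic parameters that movement carries.

    The skull landmark set may be in any world pose; the recording is produced
    in canonical head coordinates (the head-fixed frame a jaw tracker reports).
    """
    mconfig.validate()
    if movement not in MOVEMENTS:
        raise InvalidConfig(f"unknown movement {movement!r}")
    ctx = _MandibleContext.from_landmarks(skull)
    A0, B0 = ctx.cc["left"], ctx.cc["right"]
    r0 = float(np.linalg.norm(A0 - B0))
    hinge = _true_hinge_frame(ctx)
    # path directions are specified in axis-horizontal coordinates (the frame
    # all inclination parameters are measured in) and mapped back to the head
    ahs_to_head = hinge.to_ahs.rotation.T

    duration = (mconfig.opening_duration_s if movement == "open_close"
                else mconfig.excursion_duration_s)
    n_half = max(12, int(round(duration * mconfig.frame_rate / 2)) + 1)
    n_hold = max(4, n_half // 2)
    theta_h, prog_h = _half_profile(n_half, mconfig, movement)
    theta = _mirror(theta_h, n_hold)
    prog = _mirror(prog_h, n_hold)
    n = theta.shape[0]
    times = np.arange(n) / mconfig.frame_rate

    if movement == "open_close":
        slope = np.radians(mconfig.opening_slope_deg)

        def make_glide(phi):
            return ahs_to_head @ np.array([np.cos(slope) * np.cos(phi),
                                           np.cos(slope) * np.sin(phi),
                                           -np.sin(slope)])

        pl, pr = _rigid_pair_paths(
            ctx.cc, mconfig.ocpl.as_dict(),
            {"left": make_glide, "right": make_glide},
            {"left": 0.0, "right": 0.0}, prog, r0)
        spin = theta * _opening_spin_sign(ctx, A0, B0)
    elif movement == "protrusion":
        make_u = {side: (lambda phi, s=side: ahs_to_head @ _unit3(np.array(
            [1.0, np.tan(phi), -np.tan(np.radians(mconfig.sci[s]))])))
            for side in SIDES}
        # azimuth encoding the requested medial-positive transverse inclination
        phi_fixed = {side: np.radians(-_SIGN[side] * mconfig.tci[side]) for side in SIDES}
        pl, pr = _rigid_pair_paths(ctx.cc, mconfig.pcpl.as_dict(), make_u,
                                   phi_fixed, prog, r0)
        spin = theta
    else:
        working = movement.split("_")[1]
        nonworking = "right" if working == "left" else "left"
        sgn_nw = _SIGN[nonworking]
        delta = np.radians(mconfig.lateral_descent_deg)
        ba = np.radians(mconfig.bennett[nonworking])
        # non-working condyle: straight anteromedial descent at the requested
        # Bennett angle; working condyle: anterolateral pivot
        u_nw = ahs_to_head @ np.array([np.cos(delta) * np.cos(ba),
                                       -sgn_nw * np.cos(delta) * np.sin(ba),
                                       -np.sin(delta)])
        u_w = ahs_to_head @ _unit3(np.array([1.0, _SIGN[working] * 1.0, -0.25]))
        c_ext = mconfig.ncpl[nonworking] * prog
        p_nw = ctx.cc[nonworking] + np.outer(c_ext, u_nw)
        b = _coupled_extent(ctx.cc[nonworking] - ctx.cc[working], u_nw, u_w,
                            c_ext, r0)
        p_w = ctx.cc[working] + np.outer(b, u_w)
        pl, pr = (p_nw, p_w) if nonworking == "left" else (p_w, p_nw)
        # spin about the intercondylar axis is the free parameter used to meet
        # the requested incisal path length (floor-limited: the yaw the
        # non-working excursion imposes sets a minimum the spin cannot undo)
        spin = _solve_incisal_spin(ctx, hinge, A0, B0, pl, pr, prog,
                                   mconfig.nipl[nonworking])

    R, t = _poses_from_condyles(A0, B0, pl, pr, spin)
    truth = _movement_truth(movement, R, t, ctx, hinge)

    rng = np.random.default_rng(seed)
    markers = np.einsum("nij,kj->nki", R, ctx.markers) + t[:, None, :]
    incisor = np.einsum("nij,j->ni", R, ctx.incisor) + t
    if mconfig.marker_noise_sd > 0:
        markers = markers + rng.normal(0.0, mconfig.marker_noise_sd, markers.shape)
        incisor = incisor + rng.normal(0.0, mconfig.marker_noise_sd, incisor.shape)
    return MotionRecording(movement, times, markers, incisor), truth


def _unit3(v):
    return v / np.linalg.norm(v)


def _direction_from_inclinations(sci_deg, tci_deg, side):
    """Unit condylar-path direction with the given sagittal descent and signed
    transverse (medial-positive) inclination."""
    sgn = _SIGN[side]
    return _unit3(np.array([1.0, -sgn * np.tan(np.radians(tci_deg)),
                            -np.tan(np.radians(sci_deg))]))


def _solve_contralateral(delta0, u_a, a_end, b_target, r0, make_u, phi0=0.0):
    """Find the azimuth phi such that the rigidly-coupled contralateral extent
    equals ``b_target`` when the prescribed side reaches ``a_end``.

    The feasible azimuth range is one-sided and the extent map is monotone on
    it, so the bracket is located by a grid scan; when the target falls in the
    thin unreachable sliver near the feasibility edge the closest feasible
    azimuth is used instead (the realized extent is what ground truth
    records).
    """

    a_grid = np.linspace(0.0, a_end, 24)

    def g(phi):
        try:
            b = _coupled_extent(delta0, u_a, make_u(phi), a_grid, r0)
        except InvalidConfig:
            return np.nan
        # a physically valid contralateral excursion advances monotonically
        # (sub-0.02 mm backtracking is numerical wiggle near branch degeneracy)
        if b[-1] <= 0 or np.any(np.diff(b) < -0.02):
            return np.nan
        return b[-1] - b_target

    phis = phi0 + np.radians(np.linspace(-25.0, 25.0, 201))
    vals = np.array([g(p) for p in phis])
    ok = np.isfinite(vals)
    if not np.any(ok):
        raise InvalidConfig("no rigidly-compatible contralateral trajectory found")
    candidates = list(zip(phis, vals, ok))
    # refine the feasibility edges: the extent varies steeply just inside
    # them, so the bracket often hides between a feasible and an infeasible
    # grid point
    for i in range(len(phis) - 1):
        if ok[i] != ok[i + 1]:
            bad, good = (phis[i], phis[i + 1]) if ok[i + 1] else (phis[i + 1], phis[i])
            for _ in range(60):
                mid = 0.5 * (bad + good)
                if np.isfinite(g(mid)):
                    good = mid
                else:
                    bad = mid
            candidates.append((good, g(good), True))
    candidates.sort(key=lambda c: c[0])
    best = None
    for (p1, v1, k1), (p2, v2, k2) in zip(candidates, candidates[1:]):
        if k1 and k2 and v1 * v2 <= 0:
            best = _bisect_ignoring_gaps(g, p1, v1, p2, v2)
            break
    if best is None:  # target just outside the reachable set: closest feasible
        feas = [(p, v) for p, v, k in candidates if k]
        best = min(feas, key=lambda c: abs(c[1]))[0]
    return make_u(best)


def _bisect_ignoring_gaps(g, lo, glo, hi, ghi, iters=60):
    """Bisection that tolerates thin infeasible (NaN) slivers inside the
    bracket; returns the azimuth with the smallest |g| encountered."""
    best_phi, best_val = (lo, abs(glo)) if abs(glo) < abs(ghi) else (hi, abs(ghi))
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if np.isnan(gm):
            for frac in (0.45, 0.55, 0.4, 0.6, 0.3, 0.7):
                mid = lo + frac * (hi - lo)
                gm = g(mid)
                if not np.isnan(gm):
                    break
            else:
                break  # bracket interior is infeasible: keep the best edge
        if abs(gm) < best_val:
            best_phi, best_val = mid, abs(gm)
        if gm == 0.0:
            return mid
        if glo * gm < 0:
            hi, ghi = mid, gm
        else:
            lo, glo = mid, gm
    return best_phi


def _rigid_pair_paths(ccs, ext, make_u, phi_fixed, prog, r0):
    """Straight per-side condylar trajectories compatible with a rigid
    mandible: the larger-extent side is prescribed exactly, the other side's
    azimuth is solved so its extent matches too."""
    p = "left" if ext["left"] >= ext["right"] else "right"
    q = "right" if p == "left" else "left"
    delta0 = ccs[p] - ccs[q]
    u_p = make_u[p](phi_fixed[p])
    u_q = _solve_contralateral(delta0, u_p, ext[p], ext[q], r0, make_u[q],
                               phi0=phi_fixed[q])
    a = ext[p] * prog
    b = _coupled_extent(delta0, u_p, u_q, a, r0)
    if np.max(b) < 1.2:
        raise InvalidConfig(
            "rigid coupling leaves the contralateral excursion degenerate "
            f"({np.max(b):.2f} mm); the requested side combination is not realizable")
    paths = {p: ccs[p] + np.outer(a, u_p), q: ccs[q] + np.outer(b, u_q)}
    return paths["left"], paths["right"]


def _opening_spin_sign(ctx, A0, B0):
    """Spin sign about the intercondylar axis that lowers the incisal point."""
    d = _unit3(B0 - A0)
    R = Rotation.from_rotvec(d * 0.1).as_matrix()
    pivot = 0.5 * (A0 + B0)
    moved = R @ (ctx.incisor - pivot) + pivot
    return 1.0 if moved[2] < ctx.incisor[2] else -1.0


def _solve_incisal_spin(ctx, hinge, A0, B0, pl, pr, prog, target):
    """Spin amplitude (about the moving intercondylar axis) whose incisal path
    length matches the request.

    The incisal path length is convex in the spin amplitude with its minimum
    near zero spin; when the target lies below that floor — the yaw imposed by
    the condylar trajectories already moves the incisor further than requested
    — zero spin is used and ground truth records the realized value.
    """

    def nipl_of(gamma_deg):
        spin = np.radians(gamma_deg) * prog
        R, t = _poses_from_condyles(A0, B0, pl, pr, spin)
        inc = hinge.to_ahs.apply(np.einsum("nij,j->ni", R, ctx.incisor) + t)
        return path_length(inc)

    if nipl_of(0.0) >= target:
        return np.zeros_like(prog)
    hi = 2.0
    while nipl_of(hi) < target and hi < 16.0:
        hi *= 2.0
    if nipl_of(hi) < target:
        return np.radians(hi) * prog
    gamma = brentq(lambda g: nipl_of(g) - target, 0.0, hi, xtol=1e-10)
    return np.radians(gamma) * prog


def _movement_truth(movement, R, t, ctx, hinge) -> dict[str, float]:
    """True dynamic parameters: the measurement definitions applied to the
    noiseless analytic trajectories in the true axis-horizontal frame."""
    paths = {side: hinge.to_ahs.apply(np.einsum("nij,j->ni", R, ctx.cc[side]) + t)
             for side in SIDES}
    inc = hinge.to_ahs.apply(np.einsum("nij,j->ni", R, ctx.incisor) + t)
    truth: dict[str, float] = {}
    if movement == "open_close":
        for side in SIDES:
            truth[f"OCPL_{side}"] = path_length(paths[side])
    elif movement == "protrusion":
        for side in SIDES:
            truth[f"PCPL_{side}"] = path_length(paths[side])
            sci, tci = condylar_inclinations(paths[side], side)
            truth[f"SCI_{side}"] = sci
            truth[f"TCI_{side}"] = tci
    else:
        working = movement.split("_")[1]
        nonworking = "right" if working == "left" else "left"
        truth[f"NCPL_{nonworking}"] = path_length(paths[nonworking])
        truth[f"BA_{nonworking}"] = bennett_angle(paths[nonworking])
        truth[f"NIPL_{nonworking}"] = path_length(inc)
    return truth


def generate_all_motions(skull: LandmarkSet, mconfig: MotionConfig, seed: int = 0
                         ) -> tuple[dict[str, MotionRecording], dict[str, float]]:
    """All four movement recordings plus merged kinematic ground truth."""
    recordings, truth = {}, {}
    for i, movement in enumerate(MOVEMENTS):
        rec, t = generate_motion(skull, mconfig, movement, seed=seed * 7919 + i)
        recordings[movement] = rec
        truth.update(t)
    return recordings, truth


# ---------------------------------------------------------------------------
# cohort generation


#: per-side (DS, NDS) means and SDs of the emulated study conditions
DEFAULT_EFFECT_TABLE = {
    "MxH": ((49.67, 3.56), (50.45, 3.30)),
    "RH": ((45.91, 5.39), (48.40, 4.24)),
    "FRI": ((82.34, 3.70), (77.00, 3.31)),
    "LRI": ((86.41, 6.84), (83.93, 5.59)),
    "BL": ((74.62, 5.05), (75.58, 5.72)),
    "APCP": ((13.21, 3.33), (13.80, 3.16)),
    "TCP": ((52.03, 2.51), (52.77, 2.40)),
    "VCP": ((8.72, 3.07), (8.29, 3.05)),
    "AJS": ((2.13, 0.71), (1.74, 0.53)),
    "SJS": ((2.05, 0.71), (2.26, 0.93)),
    "PJS": ((1.59, 0.46), (2.01, 0.68)),
    "MJS": ((2.65, 0.69), (1.60, 0.51)),
    "LJS": ((1.48, 0.59), (1.77, 0.49)),
    "ACA": ((21.18, 6.37), (17.23, 6.00)),
    "AES": ((46.49, 9.21), (39.10, 7.39)),
    "PES": ((58.30, 9.03), (58.84, 6.60)),
    "MES": ((48.72, 12.17), (49.10, 9.29)),
    "LES": ((37.77, 7.97), (39.62, 6.73)),
    "OCPL": ((15.27, 2.75), (14.21, 3.60)),
    "PCPL": ((9.18, 1.73), (6.88, 1.64)),
    "SCI": ((44.39, 5.21), (39.57, 7.48)),
    "TCI": ((4.20, 2.86), (-2.44, 2.23)),
    "BA": ((14.39, 3.99), (9.11, 2.35)),
    "NCPL": ((8.15, 1.46), (6.12, 1.70)),
    "NIPL": ((6.59, 1.18), (5.81, 1.03)),
}

#: truncation bounds keeping drawn values inside the geometric invariants
_CLIP = {
    "MxH": (35, 65), "RH": (32, 65), "FRI": (62, 118), "LRI": (62, 118),
    "BL": (55, 95), "APCP": (4, 26), "TCP": (42, 64), "VCP": (2, 20),
    "AJS": (0.4, 6), "SJS": (0.4, 6), "PJS": (0.4, 6), "MJS": (0.4, 6),
    "LJS": (0.4, 6), "ACA": (3, 45), "AES": (18, 78), "PES": (18, 78),
    "MES": (18, 78), "LES": (18, 78), "OCPL": (6, 26), "PCPL": (3, 16),
    "SCI": (18, 68), "TCI": (-14, 14), "BA": (3, 28), "NCPL": (2.5, 14),
    "NIPL": (2.5, 12),
}


@dataclass
class EffectSpec:
    """Interside effect structure for cohort simulation.

    ``table`` maps variable name -> ((DS mean, DS sd), (NDS mean, NDS sd)).
    ``pairing_correlation`` is the latent correlation between a subject's DS
    and NDS values (not identifiable from marginal summaries; exposed as a
    parameter, default 0.5).  ``latent_loading`` ties the deviated-side values
    of ``latent_vars`` to one shared subject-level factor, inducing positive
    DS correlations among them while preserving the marginals.
    """

    table: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_EFFECT_TABLE.items()})
    pairing_correlation: float = 0.5
    latent_loading: float = 0.6
    latent_vars: tuple = ("FRI", "AES", "MJS", "ACA", "PCPL")

    def validate(self):
        if not -0.99 <= self.pairing_correlation <= 0.99:
            raise InvalidConfig("pairing correlation must lie in [-0.99, 0.99]")
        if not 0.0 <= self.latent_loading < 1.0:
            raise InvalidConfig("latent loading must lie in [0, 1)")

    @staticmethod
    def null() -> "EffectSpec":
        """All interside deltas zero (pooled means/SDs); for calibration runs."""
        table = {}
        for k, ((m1, s1), (m2, s2)) in DEFAULT_EFFECT_TABLE.items():
            m, s = 0.5 * (m1 + m2), 0.5 * (s1 + s2)
            table[k] = ((m, s), (m, s))
        return EffectSpec(table=table)


def sample_cohort_table(n_subjects: int, spec: EffectSpec | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Draw a subjects x variables table of DS/NDS parameter values.

    This is the statistical layer of cohort generation (no geometry): per-side
    Gaussians with the configured pairing correlation and deviated-side latent
    factor, truncated to the geometric invariants.
    """
    spec = spec or EffectSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    rho, lam = spec.pairing_correlation, spec.latent_loading
    f = rng.normal(size=n_subjects)  # shared deviated-side factor
    data = {}
    for var, ((m_ds, s_ds), (m_nds, s_nds)) in spec.table.items():
        e = rng.normal(size=n_subjects)
        z_ds = lam * f + np.sqrt(1.0 - lam * lam) * e if var in spec.latent_vars else e
        z_nds = rho * z_ds + np.sqrt(1.0 - rho * rho) * rng.normal(size=n_subjects)
        lo, hi = _CLIP.get(var, (-np.inf, np.inf))
        data[f"{var}_DS"] = np.clip(m_ds + s_ds * z_ds, lo, hi)
        data[f"{var}_NDS"] = np.clip(m_nds + s_nds * z_nds, lo, hi)
        if var == "SCI":
            # cap the interside inclination mismatch at a physiological 20
            # degrees; larger splits leave no rigid-body protrusion that can
            # carry both condylar paths
            data["SCI_NDS"] = np.clip(data["SCI_NDS"], data["SCI_DS"] - 20.0,
                                      data["SCI_DS"] + 20.0)
    dev_sign = np.where(rng.random(n_subjects) < 0.5, 1.0, -1.0)
    data["menton_deviation"] = dev_sign * np.clip(rng.normal(4.5, 1.5, n_subjects), 3.05, 12.0)
    data["ANB"] = -np.clip(np.abs(rng.normal(2.5, 1.2, n_subjects)), 0.1, 10.0)
    data["PogNPerp"] = np.clip(np.abs(rng.normal(2.0, 1.0, n_subjects)), 0.1, 10.0)
    return pd.DataFrame(data, index=pd.RangeIndex(n_subjects, name="subject"))


@dataclass
class SubjectSpec:
    subject_id: int
    skull: SkullConfig
    motion: MotionConfig
    deviated_side: str


def generate_cohort(n_subjects: int, effect_spec: EffectSpec | None = None,
                    seed: int = 0, marker_noise_sd: float = 0.0,
                    frame_rate: float = 30.0) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Per-subject skull/motion configurations plus the requested-value table.

    The deviated side is assigned from the sign of the drawn menton deviation
    (+ = left); DS-column draws land on that side's configuration fields.
    """
    table = sample_cohort_table(n_subjects, effect_spec, seed)
    subjects = []
    for i in range(n_subjects):
        row = table.iloc[i]
        dev = float(row["menton_deviation"])
        ds = "left" if dev > 0 else "right"

        def ps(var):
            v = {ds: float(row[f"{var}_DS"]),
                 ("right" if ds == "left" else "left"): float(row[f"{var}_NDS"])}
            return PerSide(v["left"], v["right"])

        skull = SkullConfig(
            menton_deviation=dev, maxillary_height=ps("MxH"), ramal_height=ps("RH"),
            frontal_ramal_inclination=ps("FRI"), lateral_ramal_inclination=ps("LRI"),
            body_length=ps("BL"), posture_ap=ps("APCP"), posture_transverse=ps("TCP"),
            posture_vertical=ps("VCP"), joint_space_superior=ps("SJS"),
            joint_space_anterior=ps("AJS"), joint_space_posterior=ps("PJS"),
            joint_space_medial=ps("MJS"), joint_space_lateral=ps("LJS"),
            axial_condylar_angle=ps("ACA"), eminence_anterior=ps("AES"),
            eminence_posterior=ps("PES"), eminence_medial=ps("MES"),
            eminence_lateral=ps("LES"), anb=float(row["ANB"]),
            pog_nperp=float(row["PogNPerp"]))
        motion = MotionConfig(
            ocpl=ps("OCPL"), pcpl=ps("PCPL"), sci=ps("SCI"), tci=ps("TCI"),
            ncpl=ps("NCPL"), bennett=ps("BA"), nipl=ps("NIPL"),
            marker_noise_sd=marker_noise_sd, frame_rate=frame_rate)
        subjects.append(SubjectSpec(i, skull, motion, ds))
    return subjects, table
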