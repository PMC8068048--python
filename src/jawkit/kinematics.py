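"""Jaw kinematics: terminal hinge axis estimation, axis-horizontal reference,
condylar/incisal path reconstruction, and the seven dynamic parameters.

A motion recording holds time-stamped frames of four mandibular marker points
plus an incisor point, in head-fixed coordinates, labeled by movement type
(``open_close``, ``protrusion``, ``laterotrusion_left``,
``laterotrusion_right``).  Per-frame mandibular poses come from least-squares
rigid registration of the markers against the first frame.  The terminal
hinge axis is the common screw axis of the initial pure-rotation phase of the
opening movement; the axis-horizontal plane through it is the zero reference
for all path inclinations.

Dynamic parameters (per side): OCPL (opening condylar path length), PCPL
(protrusive condylar path length), SCI/TCI (sagittal/transverse condylar
inclination of the protrusive path; TCI positive toward the medial side), BA
(Bennett angle at 1 mm of non-working condylar path), NCPL and NIPL
(non-working condylar and incisal path lengths during laterotrusion; a
laterotrusion toward one side yields the non-working parameters of the
contralateral side).

Path length is the cumulative chord length of the monotone leg from the first
frame to the frame of maximal displacement (axiographic convention for
curvilinear traces), after optional moving-average smoothing; smoothing is off
by default so noiseless analyses are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .errors import (DegenerateGeometry, DegeneratePath, MissingMovement,
                     NearIdentityRotation, NoRotationPhase, PathTooShort, SchemaError)
from .geometry import Line3, Plane, RigidTransform

MOVEMENTS = ("open_close", "protrusion", "laterotrusion_left", "laterotrusion_right")
_SIGN = {"left": 1.0, "right": -1.0}


@dataclass
class MotionRecording:
    """Time series of mandibular marker frames plus the incisor point."""

    movement: str
    times: np.ndarray      # (n,)
    markers: np.ndarray    # (n, 4, 3), head-fixed coordinates
    incisor: np.ndarray    # (n, 3)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.markers = np.asarray(self.markers, dtype=float)
        self.incisor = np.asarray(self.incisor, dtype=float)
        if self.movement not in MOVEMENTS:
            raise SchemaError(f"unknown movement label '{self.movement}'")
        n = self.times.shape[0]
        if n < 20:
            raise SchemaError(f"recording needs >= 20 frames, got {n}")
        if self.markers.shape != (n, 4, 3) or self.incisor.shape != (n, 3):
            raise SchemaError("markers must be (n, 4, 3) and incisor (n, 3)")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError("frame times must be strictly increasing")
        for i in (0, n - 1):  # spot-check marker conditioning
            sv = np.linalg.svd(self.markers[i] - self.markers[i].mean(axis=0),
                               compute_uv=False)
            if sv[1] < 1e-6:
                raise SchemaError(f"markers collinear in frame {i}")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    def poses(self) -> list[RigidTransform]:
        """Per-frame rigid pose relative to the first frame."""
        R, t = self.pose_arrays()
        return [RigidTransform(R[i], t[i]) for i in range(self.n_frames)]

    def pose_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame poses relative to the first frame, as stacked arrays."""
        return geo.batch_rigid_transforms(self.markers[0], self.markers)


@dataclass
class HingeFrame:
    """Terminal hinge axis, per-side condylar reference points on it, and the
    axis-horizontal zero-reference plane/coordinate transform."""

    hinge_axis: Line3
    condylar_reference_points: dict[str, np.ndarray]
    axis_horizontal_plane: Plane
    to_ahs: RigidTransform  # head coords -> axis-horizontal system


def hinge_frame_from_axis(axis: Line3, condylar_points: dict[str, np.ndarray],
                          vertical=np.array([0.0, 0.0, 1.0])) -> HingeFrame:
    """Build the axis-horizontal reference from a hinge axis.

    Reference points are the orthogonal projections of the per-side condylar
    points onto the axis.  The axis-horizontal plane contains the axis; its
    normal is the head-vertical direction projected orthogonal to the axis.
    Axis-horizontal coordinates: z = 0 on the plane (+z superior), y along the
    axis toward the left, x = y cross z (anterior).
    """
    refs = {s: axis.project(p) for s, p in condylar_points.items()}
    d = axis.direction
    zn = vertical - np.dot(vertical, d) * d
    if np.linalg.norm(zn) < 1e-9:
        raise DegenerateGeometry("hinge axis is parallel to head-vertical")
    zn = zn / np.linalg.norm(zn)
    y = d if (refs["left"] - refs["right"]) @ d > 0 else -d
    x = np.cross(y, zn)
    origin = 0.5 * (refs["left"] + refs["right"])
    R = np.vstack([x, y, zn])
    plane = Plane(zn, float(np.dot(zn, origin)))
    return HingeFrame(axis, refs, plane, RigidTransform(R, -R @ origin))


def estimate_hinge_axis(open_close: MotionRecording,
                        condylar_centers: dict[str, np.ndarray] | None = None,
                        rotation_window: float = 10.0,
                        angle_floor: float = 1.0,
                        pitch_tolerance: float = 0.3,
                        intercondylar_width: float = 104.0,
                        vertical=np.array([0.0, 0.0, 1.0])) -> HingeFrame:
    """Estimate the terminal hinge axis from the opening movement.

    Per-frame poses relative to frame 0 are scanned from the start; the
    initial contiguous set whose rotation angle stays within
    ``rotation_window`` degrees and whose screw-axis translation (pitch)
    component stays within ``pitch_tolerance`` mm is the terminal hinge phase.
    The axis is the rotation-angle-weighted least-squares common screw axis
    over that set.  Condylar reference points are projections of the supplied
    condylar centers onto the axis, or points at +/- half the intercondylar
    width when none are supplied.
    """
    if open_close.movement != "open_close":
        raise SchemaError("hinge axis estimation requires an open_close recording")
    R, t = open_close.pose_arrays()
    all_angles = geo.rotation_angles_deg(R)
    phase = [0]
    angles = [0.0]
    pitch_strikes = 0
    for i in range(1, open_close.n_frames):
        angle = all_angles[i]
        if angle > rotation_window:
            break
        if angle >= angle_floor and abs(
                geo._screw(R[i], t[i], angle_floor).pitch_mm) > pitch_tolerance:
            # require two consecutive violations so a single noisy frame
            # does not truncate the hinge phase
            pitch_strikes += 1
            if pitch_strikes >= 2:
                break
            continue
        pitch_strikes = 0
        phase.append(i)
        angles.append(angle)
    # common screw axis over all sufficiently-separated frame pairs of the
    # hinge phase: pairwise relative poses decouple the estimate from the
    # noise of any single reference frame
    span = max(angles)
    if span < angle_floor:
        raise NoRotationPhase("opening starts with no measurable rotation")
    sep_floor = max(angle_floor, 0.4 * span)
    axes = []
    for ii in range(len(phase)):
        for jj in range(ii + 1, len(phase)):
            if angles[jj] - angles[ii] < sep_floor:
                continue
            i, j = phase[ii], phase[jj]
            R_rel = R[j] @ R[i].T
            t_rel = t[j] - R_rel @ t[i]
            try:
                axes.append(geo._screw(R_rel, t_rel, angle_floor))
            except NearIdentityRotation:
                continue
    if len(axes) < 3:
        raise NoRotationPhase(
            "no initial pure-rotation phase found (need >= 3 qualifying pairs)")
    w = np.array([sa.angle_deg ** 2 for sa in axes])
    D = np.array([sa.axis.direction for sa in axes])
    D[D @ D[-1] < 0] *= -1.0  # sign-align before averaging
    M = (D * w[:, None]).T @ D
    evals, evecs = np.linalg.eigh(M)
    d = evecs[:, -1]
    if d @ D[-1] < 0:
        d = -d
    # weighted least-squares common point: min sum w_i |(I - P_i)(p - p_i)|^2
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for sa, wi in zip(axes, w):
        P = np.eye(3) - np.outer(sa.axis.direction, sa.axis.direction)
        A += wi * P
        b += wi * (P @ sa.axis.point)
    A += np.outer(d, d)  # pin the along-axis component (closest to origin)
    p = np.linalg.solve(A, b)
    axis = Line3(p - np.dot(p, d) * d, d)
    if condylar_centers is None:
        mid = axis.project(np.zeros(3))
        yd = d if d[1] > 0 else -d
        condylar_centers = {"left": mid + 0.5 * intercondylar_width * yd,
                            "right": mid - 0.5 * intercondylar_width * yd}
    return hinge_frame_from_axis(axis, condylar_centers, vertical=vertical)


def condylar_paths(recording: MotionRecording, hinge: HingeFrame
                   ) -> dict[str, np.ndarray]:
    """Condylar reference-point and incisal trajectories in axis-horizontal
    coordinates, one (n, 3) array per key ``left``/``right``/``incisor``."""
    R, t = recording.pose_arrays()
    out = {}
    for side, ref in hinge.condylar_reference_points.items():
        pts = np.einsum("nij,j->ni", R, ref) + t
        out[side] = hinge.to_ahs.apply(pts)
    out["incisor"] = hinge.to_ahs.apply(recording.incisor)
    return out


def smooth_path(path: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with an odd window; shrinks at the edges.
    ``window <= 1`` returns the path unchanged."""
    if window <= 1:
        return np.asarray(path, dtype=float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    p = np.asarray(path, dtype=float)
    half = window // 2
    n = p.shape[0]
    cum = np.vstack([np.zeros((1, p.shape[1])), np.cumsum(p, axis=0)])
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    return (cum[hi] - cum[lo]) / (hi - lo)[:, None]


def _monotone_leg(path: np.ndarray) -> np.ndarray:
    disp = np.linalg.norm(path - path[0], axis=1)
    return path[: int(np.argmax(disp)) + 1]


def path_length(path: np.ndarray, smoothing_window: int = 0) -> float:
    """Cumulative chord length of the monotone leg from the first frame to the
    frame of maximal displacement, after optional smoothing."""
    p = np.asarray(path, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        return 0.0
    leg = _monotone_leg(smooth_path(p, smoothing_window))
    return float(np.sum(np.linalg.norm(np.diff(leg, axis=0), axis=1)))


def condylar_inclinations(protrusive_path: np.ndarray, side: str,
                          smoothing_window: int = 0) -> tuple[float, float]:
    """(SCI, TCI) of a protrusive condylar path in axis-horizontal coordinates.

    SCI is the angle between the total-least-squares line of the sagittal
    (x-z) projection of the monotone leg and the axis-horizontal plane, in
    [0, 90].  TCI is the signed angle of the axial (x-y) projection of that
    line versus the anterior (+x) direction, positive toward the medial side.
    """
    leg = _monotone_leg(smooth_path(np.asarray(protrusive_path, dtype=float),
                                    smoothing_window))
    if leg.shape[0] < 2 or np.linalg.norm(leg[-1] - leg[0]) < 1.0:
        raise DegeneratePath("protrusive path extent below 1 mm")
    sag = leg.copy()
    sag[:, 1] = 0.0
    sci = geo.angle_line_plane(geo.fit_line(sag).line,
                               Plane(np.array([0.0, 0.0, 1.0]), 0.0))
    axial = leg.copy()
    axial[:, 2] = 0.0
    d = geo.fit_line(axial).line.direction
    if d[0] < 0:  # orient anteriorly
        d = -d
    if abs(d[0]) < 1e-9:
        raise DegeneratePath("protrusive path has no anterior component in axial view")
    tci = -_SIGN[side] * float(np.degrees(np.arctan2(d[1], d[0])))
    return sci, tci


def bennett_angle(nonworking_path: np.ndarray, smoothing_window: int = 0,
                  chord_mm: float = 1.0) -> float:
    """Bennett angle: axial-plane angle between the anterior (+x) direction
    and the chord from the path start to the point at ``chord_mm`` of
    cumulative path length (located by linear interpolation)."""
    leg = _monotone_leg(smooth_path(np.asarray(nonworking_path, dtype=float),
                                    smoothing_window))
    seg = np.linalg.norm(np.diff(leg, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < chord_mm:
        raise PathTooShort(f"path length {cum[-1]:.3f} mm < {chord_mm} mm")
    i = int(np.searchsorted(cum, chord_mm))
    f = (chord_mm - cum[i - 1]) / (cum[i] - cum[i - 1])
    target = leg[i - 1] + f * (leg[i] - leg[i - 1])
    chord = (target - leg[0])[:2]
    if np.linalg.norm(chord) < 1e-9:
        raise DegeneratePath("degenerate axial chord at the Bennett measurement point")
    return abs(float(np.degrees(np.arctan2(chord[1], chord[0]))))


@dataclass
class KinematicRecord:
    """Per-side dynamic parameters (lengths mm, angles degrees)."""

    ocpl: dict[str, float]
    pcpl: dict[str, float]
    sci: dict[str, float]
    tci: dict[str, float]
    ba: dict[str, float]
    ncpl: dict[str, float]
    nipl: dict[str, float]

    def side_values(self, side: str) -> dict[str, float]:
        return {"OCPL": self.ocpl[side], "PCPL": self.pcpl[side],
                "SCI": self.sci[side], "TCI": self.tci[side], "BA": self.ba[side],
                "NCPL": self.ncpl[side], "NIPL": self.nipl[side]}


def kinematic_record(recordings: dict[str, MotionRecording], hinge: HingeFrame,
                     smoothing_window: int = 0,
                     bennett_smoothing_window: int | None = None) -> KinematicRecord:
    """All seven dynamic parameters per side from the four movement recordings.

    For a laterotrusion toward side W, the non-working parameters (NCPL, BA
    from the condylar path; NIPL from the incisal path) are assigned to the
    contralateral (balancing) side.

    The Bennett chord (1 mm from the start) is far more noise-sensitive than
    the path integrals, and the early non-working path is straight, so the
    Bennett measurement tolerates much heavier smoothing without bias; its
    window defaults to 4x the general one (``None``) but can be set
    explicitly.
    """
    for m in MOVEMENTS:
        if m not in recordings:
            raise MissingMovement(f"missing required movement recording '{m}'")
    w = smoothing_window
    if bennett_smoothing_window is None:
        bennett_smoothing_window = 4 * w + 1 if w > 0 else 0
    wb = bennett_smoothing_window
    ocpl, pcpl, sci, tci, ba, ncpl, nipl = ({} for _ in range(7))
    paths = condylar_paths(recordings["open_close"], hinge)
    for side in ("left", "right"):
        ocpl[side] = path_length(paths[side], w)
    paths = condylar_paths(recordings["protrusion"], hinge)
    for side in ("left", "right"):
        pcpl[side] = path_length(paths[side], w)
        sci[side], tci[side] = condylar_inclinations(paths[side], side, w)
    for working, nonworking in (("left", "right"), ("right", "left")):
        paths = condylar_paths(recordings[f"laterotrusion_{working}"], hinge)
        ncpl[nonworking] = path_length(paths[nonworking], w)
        ba[nonworking] = bennett_angle(paths[nonworking], wb)
        nipl[nonworking] = path_length(paths["incisor"], w)
    return KinematicRecord(ocpl, pcpl, sci, tci, ba, ncpl, nipl)
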