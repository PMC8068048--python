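"""TMJ morphometry: condylar center, extracapsular posture, intracapsular
joint spaces, axial condylar angle and articular-eminence steepness, per side.

Inputs are a condyle description (medial/lateral poles, an axial outline
polyline at pole level, the highest point of the condyle) and a glenoid-fossa
description (the highest point of its superior wall and four wall profile
polylines).  All measurements are taken in the canonical head system of a
:class:`~jawkit.cranio.HeadFrame`, so they are invariant under rigid motion of
the world coordinates.

Measurement conventions (the source protocol names tangent lines but not the
slice, so these are fixed here and documented):

* the condylar center (CC) is the intersection of the two chord-supporting
  lines of maximal extent along the pole-to-pole direction and its in-plane
  perpendicular, in the axial projection at pole level;
* anterior/posterior joint spaces are minimal distances from the anterior-most
  / posterior-most outline point to the corresponding wall profile in the
  sagittal (x-z) projection through CC; medial/lateral spaces likewise in the
  coronal (y-z) projection;
* the superior joint space is the vertical gap between the condylar highest
  point and the FH-parallel tangent at the fossa roof point;
* eminence steepness angles come from total-least-squares lines through the
  projected wall profiles versus the FH plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .cranio import SIDES, HeadFrame, LandmarkSet, _SIGN, _SUFFIX
from .errors import DegenerateGeometry, ProfileGapError
from .geometry import Plane

FOSSA_WALLS = ("anterior", "posterior", "medial", "lateral")


@dataclass
class CondyleGeometry:
    side: str
    medial_pole: np.ndarray
    lateral_pole: np.ndarray
    axial_outline: np.ndarray  # (n >= 8, 3) ordered polyline at pole level
    highest_point: np.ndarray

    def __post_init__(self):
        self.medial_pole = np.asarray(self.medial_pole, dtype=float).reshape(3)
        self.lateral_pole = np.asarray(self.lateral_pole, dtype=float).reshape(3)
        self.axial_outline = np.asarray(self.axial_outline, dtype=float).reshape(-1, 3)
        self.highest_point = np.asarray(self.highest_point, dtype=float).reshape(3)
        if self.axial_outline.shape[0] < 8:
            raise DegenerateGeometry("condylar outline needs at least 8 points")


@dataclass
class FossaGeometry:
    side: str
    roof_point: np.ndarray  # highest point of the superior wall
    wall_profiles: dict[str, np.ndarray]  # wall -> (n >= 5, 3) ordered polyline

    def __post_init__(self):
        self.roof_point = np.asarray(self.roof_point, dtype=float).reshape(3)
        self.wall_profiles = {k: np.asarray(v, dtype=float).reshape(-1, 3)
                              for k, v in self.wall_profiles.items()}
        for wall in FOSSA_WALLS:
            if wall not in self.wall_profiles:
                raise DegenerateGeometry(f"missing {wall} wall profile")
            if self.wall_profiles[wall].shape[0] < 5:
                raise DegenerateGeometry(f"{wall} wall profile needs at least 5 points")


@dataclass
class TmjRecord:
    """Per-side TMJ morphometric parameters (distances mm, angles degrees)."""

    apcp: dict[str, float]
    tcp: dict[str, float]
    vcp: dict[str, float]
    sjs: dict[str, float]
    ajs: dict[str, float]
    pjs: dict[str, float]
    mjs: dict[str, float]
    ljs: dict[str, float]
    aca: dict[str, float]
    aca_sign: dict[str, int]
    aes: dict[str, float]
    pes: dict[str, float]
    mes: dict[str, float]
    les: dict[str, float]

    def side_values(self, side: str) -> dict[str, float]:
        return {"APCP": self.apcp[side], "TCP": self.tcp[side], "VCP": self.vcp[side],
                "AJS": self.ajs[side], "SJS": self.sjs[side], "PJS": self.pjs[side],
                "MJS": self.mjs[side], "LJS": self.ljs[side], "ACA": self.aca[side],
                "AES": self.aes[side], "PES": self.pes[side], "MES": self.mes[side],
                "LES": self.les[side]}


def condyle_from_landmarks(landmarks: LandmarkSet, side: str) -> CondyleGeometry:
    sfx = _SUFFIX[side]
    return CondyleGeometry(side,
                           landmarks.get("CondPoleMed" + sfx),
                           landmarks.get("CondPoleLat" + sfx),
                           landmarks.profile(side, "condyle_outline"),
                           landmarks.get("Co" + sfx))


def fossa_from_landmarks(landmarks: LandmarkSet, side: str) -> FossaGeometry:
    return FossaGeometry(side, landmarks.get("FossaRoof" + _SUFFIX[side]),
                         {w: landmarks.profile(side, f"fossa_{w}") for w in FOSSA_WALLS})


def _chs(geom, frame: HeadFrame):
    """Re-express a condyle/fossa geometry in canonical head coordinates."""
    T = frame.to_chs
    if isinstance(geom, CondyleGeometry):
        return CondyleGeometry(geom.side, T.apply(geom.medial_pole),
                               T.apply(geom.lateral_pole), T.apply(geom.axial_outline),
                               T.apply(geom.highest_point))
    return FossaGeometry(geom.side, T.apply(geom.roof_point),
                         {k: T.apply(v) for k, v in geom.wall_profiles.items()})


def _extreme_chord(outline_xy: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two outline vertices of maximal mutual extent along direction ``u``
    (equivalently the brute-force maximum of |(p - q) . u| over vertex pairs)."""
    proj = outline_xy @ u
    return outline_xy[int(np.argmax(proj))], outline_xy[int(np.argmin(proj))]


def _intersect_lines_2d(p1, d1, p2, d2) -> np.ndarray:
    A = np.column_stack([d1, -d2])
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        raise DegenerateGeometry("width chords are parallel")
    s = np.linalg.solve(A, p2 - p1)
    return p1 + s[0] * d1


def condyle_center(geom: CondyleGeometry, frame: HeadFrame) -> np.ndarray:
    """Center of the condyle (CC): intersection, in the axial projection at
    pole level, of the supporting lines of the largest lateromedial and the
    largest anteroposterior chords of the outline.  Returned in CHS."""
    g = _chs(geom, frame)
    out = g.axial_outline[:, :2]
    u = (g.lateral_pole - g.medial_pole)[:2]
    if np.linalg.norm(u) < 1e-9:
        raise DegenerateGeometry("condylar poles coincide in axial projection")
    u = u / np.linalg.norm(u)
    v = np.array([-u[1], u[0]])
    a1, a2 = _extreme_chord(out, u)
    b1, b2 = _extreme_chord(out, v)
    if abs((a1 - a2) @ u) < 1.0 or abs((b1 - b2) @ v) < 1.0:
        raise DegenerateGeometry("condylar width below 1 mm")
    cc_xy = _intersect_lines_2d(a1, _norm2(a2 - a1), b1, _norm2(b2 - b1))
    z = 0.5 * (g.medial_pole[2] + g.lateral_pole[2])  # pole-level slice
    return np.array([cc_xy[0], cc_xy[1], z])


def _norm2(v):
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometry("zero-length chord")
    return v / n


def condylar_posture(cc: np.ndarray, frame: HeadFrame) -> tuple[float, float, float]:
    """(APCP, TCP, VCP): unsigned distances from CC (given in CHS) to the
    coronal, midsagittal and FH planes respectively."""
    cc = np.asarray(cc, dtype=float)
    return abs(float(cc[0])), abs(float(cc[1])), abs(float(cc[2]))


def _min_dist_to_polyline_2d(p: np.ndarray, poly: np.ndarray
                             ) -> tuple[float, np.ndarray, bool]:
    """Minimal distance from 2D point ``p`` to a polyline; returns (distance,
    nearest point, nearest-is-polyline-endpoint)."""
    best, best_q, best_end = np.inf, None, False
    n = poly.shape[0]
    for i in range(n - 1):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        L2 = ab @ ab
        t = 0.0 if L2 < 1e-18 else float(np.clip((p - a) @ ab / L2, 0.0, 1.0))
        q = a + t * ab
        d = float(np.linalg.norm(p - q))
        if d < best:
            best, best_q = d, q
            best_end = (i == 0 and t == 0.0) or (i == n - 2 and t == 1.0)
    return best, best_q, best_end


def _space(prominence: np.ndarray, wall: np.ndarray, idx: tuple[int, int],
           direction: np.ndarray, label: str, gap_angle_deg: float) -> float:
    """Minimal gap from a condylar prominence to a wall profile in a coordinate
    projection.  Raises ``ProfileGapError`` when the nearest profile point is a
    polyline endpoint lying more than ``gap_angle_deg`` off the measurement
    direction, i.e. the profile does not cover the measured sector."""
    p2 = prominence[list(idx)]
    w2 = wall[:, list(idx)]
    d, q, at_end = _min_dist_to_polyline_2d(p2, w2)
    if d < 1e-12:
        raise DegenerateGeometry(f"{label}: condyle touches the wall profile")
    if at_end:
        off = np.degrees(np.arccos(np.clip((q - p2) @ direction / d, -1.0, 1.0)))
        if off > gap_angle_deg:
            raise ProfileGapError(
                f"{label}: nearest wall point is a profile endpoint {off:.1f} deg "
                f"off the measurement direction (> {gap_angle_deg} deg)")
    return d


def joint_spaces(condyle: CondyleGeometry, fossa: FossaGeometry, frame: HeadFrame,
                 gap_angle_deg: float = 30.0) -> tuple[float, float, float, float, float]:
    """(SJS, AJS, PJS, MJS, LJS) for one side, in mm."""
    c = _chs(condyle, frame)
    f = _chs(fossa, frame)
    sgn = _SIGN[condyle.side]
    out = c.axial_outline
    anterior = out[int(np.argmax(out[:, 0]))]
    posterior = out[int(np.argmin(out[:, 0]))]
    medial = out[int(np.argmin(sgn * out[:, 1]))]   # toward the midline
    lateral = out[int(np.argmax(sgn * out[:, 1]))]
    sjs = float(f.roof_point[2] - c.highest_point[2])
    if sjs <= 0:
        raise DegenerateGeometry("fossa roof is not above the condylar highest point")
    ajs = _space(anterior, f.wall_profiles["anterior"], (0, 2),
                 np.array([1.0, 0.0]), "AJS", gap_angle_deg)
    pjs = _space(posterior, f.wall_profiles["posterior"], (0, 2),
                 np.array([-1.0, 0.0]), "PJS", gap_angle_deg)
    mjs = _space(medial, f.wall_profiles["medial"], (1, 2),
                 np.array([-sgn, 0.0]), "MJS", gap_angle_deg)
    ljs = _space(lateral, f.wall_profiles["lateral"], (1, 2),
                 np.array([sgn, 0.0]), "LJS", gap_angle_deg)
    return sjs, ajs, pjs, mjs, ljs


def axial_condylar_angle(condyle: CondyleGeometry, frame: HeadFrame
                         ) -> tuple[float, int]:
    """(ACA magnitude in degrees, sign) where the sign is +1 when the medial
    pole lies posterior to the lateral pole (the common presentation)."""
    c = _chs(condyle, frame)
    w = (c.lateral_pole - c.medial_pole)[:2]
    n = np.linalg.norm(w)
    if n < 1e-9:
        raise DegenerateGeometry("condylar poles coincide in axial projection")
    mag = float(np.degrees(np.arccos(np.clip(abs(w[1]) / n, 0.0, 1.0))))
    sign = 1 if c.medial_pole[0] < c.lateral_pole[0] else -1
    return mag, sign


def eminence_steepness(fossa: FossaGeometry, frame: HeadFrame
                       ) -> tuple[float, float, float, float]:
    """(AES, PES, MES, LES): best-fit-line steepness of the four wall profiles
    versus the FH plane, degrees in (0, 90)."""
    f = _chs(fossa, frame)
    fh = Plane(np.array([0.0, 0.0, 1.0]), 0.0)
    out = []
    for wall, idx in (("anterior", 0), ("posterior", 0), ("medial", 1), ("lateral", 1)):
        prof = f.wall_profiles[wall].copy()
        prof[:, 1 - idx] = 0.0  # sagittal projection for A/P walls, coronal for M/L
        ang = geo.angle_line_plane(geo.fit_line(prof).line, fh)
        if ang >= 90.0 - 1e-9:
            raise DegenerateGeometry(f"{wall} wall is vertical; steepness undefined")
        out.append(ang)
    return tuple(out)


def tmj_record(landmarks: LandmarkSet, frame: HeadFrame,
               gap_angle_deg: float = 30.0) -> TmjRecord:
    """All TMJ morphometric parameters for both sides of one subject."""
    vals = {k: {} for k in ("apcp", "tcp", "vcp", "sjs", "ajs", "pjs", "mjs",
                            "ljs", "aca", "aca_sign", "aes", "pes", "mes", "les")}
    for side in SIDES:
        condyle = condyle_from_landmarks(landmarks, side)
        fossa = fossa_from_landmarks(landmarks, side)
        cc = condyle_center(condyle, frame)
        apcp, tcp, vcp = condylar_posture(cc, frame)
        sjs, ajs, pjs, mjs, ljs = joint_spaces(condyle, fossa, frame, gap_angle_deg)
        aca, aca_sign = axial_condylar_angle(condyle, frame)
        aes, pes, mes, les = eminence_steepness(fossa, frame)
        for k, v in (("apcp", apcp), ("tcp", tcp), ("vcp", vcp), ("sjs", sjs),
                     ("ajs", ajs), ("pjs", pjs), ("mjs", mjs), ("ljs", ljs),
                     ("aca", aca), ("aca_sign", aca_sign), ("aes", aes),
                     ("pes", pes), ("mes", mes), ("les", les)):
            vals[k][side] = v
    return TmjRecord(**vals)


def condylar_centers(landmarks: LandmarkSet, frame: HeadFrame) -> dict[str, np.ndarray]:
    """Condylar centers for both sides, in CHS (used as kinematic reference points)."""
    return {side: condyle_center(condyle_from_landmarks(landmarks, side), frame)
            for side in SIDES}
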