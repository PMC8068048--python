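"""Craniofacial morphometry: reference planes, the five craniofacial
parameters, menton deviation / side assignment, and the eligibility filter.

Reference frame
---------------
The Frankfurt horizontal (FH) plane passes through both porions and the left
orbitale; the midsagittal reference (MSR) plane is perpendicular to FH through
nasion and basion; the coronal reference plane is perpendicular to both,
through basion.  All measurements are taken in the canonical head system (CHS)
these planes induce: FH = {z = 0} with +z superior, MSR = {y = 0} with +y
toward the patient's left, coronal = {x = 0} with +x anterior.  Every reported
value is therefore invariant under rigid motion of the input coordinates.

Landmark vocabulary
-------------------
The bony landmarks consumed here are named points in a :class:`LandmarkSet`:
midline ``Na, Ba, Me, A, B, Pog``; frame ``PoR, PoL, OrL``; and per side
(suffix ``_L`` / ``_R``) ``U6`` (maxillary first-molar central fossa), ``Co``
(highest point of the condyle), ``Go`` (gonion), and the two-point ramus
border pairs ``RamusLatSup/RamusLatInf`` (lateral border, for the frontal
ramal inclination) and ``RamusPostSup/RamusPostInf`` (posterior border, for
the lateral ramal inclination).  The border pairs are explicit inputs: the
source imaging protocol identifies the borders on the reconstruction, and
making them named points keeps the measurement free of hidden segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .errors import AmbiguousSide, DegenerateGeometry, MissingLandmark
from .geometry import Plane, RigidTransform

SIDES = ("left", "right")
_SUFFIX = {"left": "_L", "right": "_R"}
_SIGN = {"left": 1.0, "right": -1.0}  # CHS y-sign of each side

#: landmark names required to build the head frame
FRAME_LANDMARKS = ("PoR", "PoL", "OrL", "Na", "Ba")
#: per-side landmark stems required by the craniofacial parameters
CRANIO_SIDE_LANDMARKS = ("U6", "Co", "Go", "RamusLatSup", "RamusLatInf",
                         "RamusPostSup", "RamusPostInf")


@dataclass
class LandmarkSet:
    """Named 3D points plus per-side surface profile polylines for one subject."""

    points: dict[str, np.ndarray]
    profiles: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        self.profiles = {k: np.asarray(v, dtype=float).reshape(-1, 3)
                         for k, v in self.profiles.items()}

    def get(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmark(f"required landmark '{name}' is missing") from None

    def side_point(self, stem: str, side: str) -> np.ndarray:
        return self.get(stem + _SUFFIX[side])

    def profile(self, side: str, name: str) -> np.ndarray:
        try:
            return self.profiles[(side, name)]
        except KeyError:
            raise MissingLandmark(f"required profile '{name}' ({side}) is missing") from None

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: T.apply(v) for k, v in self.points.items()},
                           {k: T.apply(v) for k, v in self.profiles.items()})


@dataclass(frozen=True)
class HeadFrame:
    """FH/MSR/coronal reference planes and the world->CHS transform they induce."""

    fh_plane: Plane
    msr_plane: Plane
    coronal_plane: Plane
    to_chs: RigidTransform


def build_head_frame(landmarks: LandmarkSet) -> HeadFrame:
    """Construct the reference planes and the canonical head transform.

    Orientation is resolved from the landmark names: +y points from the right
    porion toward the left porion, +x toward the orbitale (anterior), and
    +z = x cross y (superior).
    """
    por = landmarks.get("PoR")
    pol = landmarks.get("PoL")
    orl = landmarks.get("OrL")
    na = landmarks.get("Na")
    ba = landmarks.get("Ba")

    geo.plane_from_points(por, pol, orl)  # raises DegenerateGeometry if collinear
    y0 = geo._unit(pol - por)
    x_hint = orl - 0.5 * (por + pol)
    x0 = x_hint - np.dot(x_hint, y0) * y0
    if np.linalg.norm(x0) < 1e-9:
        raise DegenerateGeometry("orbitale lies on the interporion axis")
    x0 = x0 / np.linalg.norm(x0)
    z_axis = np.cross(x0, y0)  # superior unit normal of FH
    fh = Plane(z_axis, float(np.dot(z_axis, por)))

    nb = na - ba
    msr_n = np.cross(z_axis, nb)
    if np.linalg.norm(msr_n) < 1e-9:
        raise DegenerateGeometry("Na-Ba direction is parallel to the FH normal")
    msr_n = msr_n / np.linalg.norm(msr_n)
    if np.dot(msr_n, y0) < 0:
        msr_n = -msr_n
    msr = Plane(msr_n, float(np.dot(msr_n, ba)))

    x_axis = np.cross(msr_n, z_axis)  # y cross z = x, anterior
    coronal = Plane(x_axis, float(np.dot(x_axis, ba)))

    R = np.vstack([x_axis, msr_n, z_axis])
    # CHS origin: intersection of the three planes
    origin = np.linalg.solve(R, np.array([coronal.offset, msr.offset, fh.offset]))
    return HeadFrame(fh, msr, coronal, RigidTransform(R, -R @ origin))


@dataclass
class CranioRecord:
    """Per-side craniofacial parameters plus midline asymmetry/eligibility inputs."""

    mxh: dict[str, float]
    rh: dict[str, float]
    fri: dict[str, float]
    lri: dict[str, float]
    bl: dict[str, float]
    menton_deviation: float
    deviated_side: str
    anb: float
    pog_nperp: float

    def side_values(self, side: str) -> dict[str, float]:
        return {"MxH": self.mxh[side], "RH": self.rh[side], "FRI": self.fri[side],
                "LRI": self.lri[side], "BL": self.bl[side]}


def _border_angle(sup: np.ndarray, inf: np.ndarray, idx: tuple[int, int],
                  ray: np.ndarray) -> float:
    """Angle in (0, 180) between a reference ray and the inferior-to-superior
    border direction, both projected onto the coordinate plane kept by ``idx``.

    The acute/obtuse distinction as projected is preserved (no folding to 90),
    matching how ramal inclinations near but not at 90 degrees are read off.
    """
    d = (sup - inf)[list(idx)]
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise DegenerateGeometry("border points coincide in projection")
    d = d / n
    if d[1] < 0:  # orient inferior -> superior (second index is z)
        d = -d
    return float(np.degrees(np.arccos(np.clip(np.dot(d, ray), -1.0, 1.0))))


def craniofacial_params(landmarks: LandmarkSet, frame: HeadFrame) -> CranioRecord:
    """Compute MxH, RH, FRI, LRI, BL per side plus menton deviation, ANB and
    Pog to N-perpendicular distance, all in the canonical head system."""
    lm = landmarks.transformed(frame.to_chs)
    mxh, rh, fri, lri, bl = {}, {}, {}, {}, {}
    me = lm.get("Me")
    for side in SIDES:
        sgn = _SIGN[side]
        u6 = lm.side_point("U6", side)
        co = lm.side_point("Co", side)
        go = lm.side_point("Go", side)
        mxh[side] = abs(float(u6[2]))
        rh[side] = float(np.linalg.norm(co - go))
        # FRI: frontal (y-z) view, lateral border vs the FH trace, measured
        # from the ray pointing laterally (away from the midline)
        fri[side] = _border_angle(lm.side_point("RamusLatSup", side),
                                  lm.side_point("RamusLatInf", side),
                                  (1, 2), np.array([sgn, 0.0]))
        # LRI: sagittal (x-z) view, posterior border vs the FH trace, measured
        # from the anterior ray
        lri[side] = _border_angle(lm.side_point("RamusPostSup", side),
                                  lm.side_point("RamusPostInf", side),
                                  (0, 2), np.array([1.0, 0.0]))
        bl[side] = float(np.linalg.norm((me - go)[:2]))  # axial view
    deviation, deviated = menton_deviation_and_sides(landmarks, frame)
    na = lm.get("Na")
    anb = _anb_angle(lm.get("A"), lm.get("B"), na)
    pog_nperp = float(lm.get("Pog")[0] - na[0])
    return CranioRecord(mxh, rh, fri, lri, bl, deviation, deviated, anb, pog_nperp)


def _anb_angle(a: np.ndarray, b: np.ndarray, na: np.ndarray) -> float:
    """ANB in the sagittal (x-z) projection: angle of A minus angle of B, each
    measured at nasion from the downward vertical toward anterior.  Negative
    when the B point is more anterior than the A point (class III)."""
    ang_a = np.arctan2(a[0] - na[0], na[2] - a[2])
    ang_b = np.arctan2(b[0] - na[0], na[2] - b[2])
    return float(np.degrees(ang_a - ang_b))


def menton_deviation_and_sides(landmarks: LandmarkSet, frame: HeadFrame
                               ) -> tuple[float, str]:
    """Signed menton deviation from the MSR plane (+ toward the left) and the
    deviated side it implies."""
    me = frame.to_chs.apply(landmarks.get("Me"))
    y = float(me[1])
    if abs(y) < 1e-9:
        raise AmbiguousSide("menton lies on the midsagittal plane")
    return y, ("left" if y > 0 else "right")


def eligibility(record: CranioRecord) -> tuple[bool, list[str]]:
    """Inclusion filter: |menton deviation| > 3 mm (facial asymmetry), Pog to
    N-perpendicular > 0 mm and ANB < 0 deg (mandibular prognathism).

    Returns (passed, reasons-for-failure)."""
    reasons = []
    if not abs(record.menton_deviation) > 3.0:
        reasons.append(f"menton deviation |{record.menton_deviation:.2f}| mm not > 3 mm")
    if not record.pog_nperp > 0.0:
        reasons.append(f"Pog-NPerp {record.pog_nperp:.2f} mm not > 0 (not prognathic)")
    if not record.anb < 0.0:
        reasons.append(f"ANB {record.anb:.2f} deg not < 0")
    return (len(reasons) == 0, reasons)
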