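"""File formats: landmark/profile CSV and JSON, trajectory CSV, report writers.

Landmark points file (CSV): header ``name,x,y,z``; one named point per row,
coordinates in mm.  Profile file (CSV): header ``side,profile,x,y,z`` with
ordered rows per (side, profile) polyline; sides are ``left``/``right``,
profile names ``condyle_outline`` and ``fossa_{anterior,posterior,medial,
lateral}``.  The JSON alternative holds both in one document::

    {"points": {"Na": [x, y, z], ...},
     "profiles": {"left": {"condyle_outline": [[x, y, z], ...], ...}, ...}}

Trajectory file (CSV): a first comment line ``# movement=<label>`` followed by
the fixed header ``time,m1x,m1y,m1z,m2x,...,m4z,incx,incy,incz`` and one row
per frame.  All schema violations raise :class:`~jawkit.errors.SchemaError`
naming the offending row/field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cranio import LandmarkSet
from .errors import SchemaError
from .kinematics import MOVEMENTS, MotionRecording

TRAJECTORY_COLUMNS = ["time"] + [f"m{i}{ax}" for i in range(1, 5) for ax in "xyz"] \
    + ["incx", "incy", "incz"]


def write_landmarks(lm: LandmarkSet, points_path, profiles_path=None) -> None:
    rows = [{"name": k, "x": v[0], "y": v[1], "z": v[2]} for k, v in sorted(lm.points.items())]
    pd.DataFrame(rows).to_csv(points_path, index=False, float_format="%.9f")
    if profiles_path is not None:
        prows = []
        for (side, name), arr in sorted(lm.profiles.items()):
            for p in arr:
                prows.append({"side": side, "profile": name,
                              "x": p[0], "y": p[1], "z": p[2]})
        pd.DataFrame(prows).to_csv(profiles_path, index=False, float_format="%.9f")


def read_landmarks(points_path, profiles_path=None) -> LandmarkSet:
    df = _read_csv(points_path, ["name", "x", "y", "z"])
    points = {}
    for i, row in df.iterrows():
        name = str(row["name"])
        if name in points:
            raise SchemaError(f"{points_path}: duplicate landmark '{name}' at row {i + 2}")
        points[name] = _coords(row, points_path, i)
    profiles = {}
    if profiles_path is not None:
        pf = _read_csv(profiles_path, ["side", "profile", "x", "y", "z"])
        for (side, name), grp in pf.groupby(["side", "profile"], sort=False):
            if side not in ("left", "right"):
                raise SchemaError(f"{profiles_path}: unknown side '{side}'")
            profiles[(side, name)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return LandmarkSet(points, profiles)


def write_landmarks_json(lm: LandmarkSet, path) -> None:
    doc = {"points": {k: list(map(float, v)) for k, v in sorted(lm.points.items())},
           "profiles": {}}
    for (side, name), arr in sorted(lm.profiles.items()):
        doc["profiles"].setdefault(side, {})[name] = arr.tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def read_landmarks_json(path) -> LandmarkSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: invalid JSON ({e})") from None
    if "points" not in doc:
        raise SchemaError(f"{path}: missing 'points' object")
    points = {k: np.asarray(v, dtype=float) for k, v in doc["points"].items()}
    for k, v in points.items():
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise SchemaError(f"{path}: point '{k}' is not a finite 3-vector")
    profiles = {}
    for side, d in doc.get("profiles", {}).items():
        for name, arr in d.items():
            profiles[(side, name)] = np.asarray(arr, dtype=float)
    return LandmarkSet(points, profiles)


def write_trajectory(rec: MotionRecording, path) -> None:
    data = np.column_stack([rec.times, rec.markers.reshape(rec.n_frames, 12), rec.incisor])
    with open(path, "w") as fh:
        fh.write(f"# movement={rec.movement}\n")
        fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
        for row in data:
            fh.write(",".join(f"{v:.9f}" for v in row) + "\n")


def read_trajectory(path) -> MotionRecording:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# movement="):
            raise SchemaError(f"{path}: line 1 must be '# movement=<label>'")
        movement = first.split("=", 1)[1]
        if movement not in MOVEMENTS:
            raise SchemaError(f"{path}: unknown movement label '{movement}'")
        try:
            df = pd.read_csv(fh)
        except Exception as e:
            raise SchemaError(f"{path}: unreadable trajectory table ({e})") from None
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise SchemaError(f"{path}: columns must be exactly {TRAJECTORY_COLUMNS}")
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        r, c = bad[0]
        raise SchemaError(f"{path}: non-finite value in row {r + 3}, "
                          f"column '{TRAJECTORY_COLUMNS[c]}'")
    times = arr[:, 0]
    if np.any(np.diff(times) <= 0):
        r = int(np.argmax(np.diff(times) <= 0))
        raise SchemaError(f"{path}: non-increasing time at row {r + 4}")
    return MotionRecording(movement, times, arr[:, 1:13].reshape(-1, 4, 3), arr[:, 13:16])


def _read_csv(path, required_cols):
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise SchemaError(f"{path}: unreadable CSV ({e})") from None
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _coords(row, path, i):
    v = np.array([row["x"], row["y"], row["z"]], dtype=float)
    if not np.all(np.isfinite(v)):
        raise SchemaError(f"{path}: non-finite coordinate at row {i + 2} "
                          f"('{row['name']}')")
    return v
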