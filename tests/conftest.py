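import numpy as np
import pytest

from jawkit import cranio, kinematics as kin, synth, tmj


@pytest.fixture(scope="session")
def default_subject():
    """One default asymmetric subject: landmarks (random world pose), all four
    noiseless motion recordings, and full ground truth."""
    skull_cfg = synth.SkullConfig()
    lm, truth = synth.generate_skull(skull_cfg, seed=11, world_pose="random")
    recs, ktruth = synth.generate_all_motions(lm, synth.MotionConfig(), seed=13)
    truth = dict(truth)
    truth.update(ktruth)
    return lm, recs, truth


@pytest.fixture(scope="session")
def measured_default(default_subject):
    lm, recs, truth = default_subject
    frame = cranio.build_head_frame(lm)
    chs = lm.transformed(frame.to_chs)
    cc = tmj.condylar_centers(chs, cranio.build_head_frame(chs))
    hinge = kin.estimate_hinge_axis(recs["open_close"], condylar_centers=cc)
    return {
        "frame": frame,
        "cranio": cranio.craniofacial_params(lm, frame),
        "tmj": tmj.tmj_record(lm, frame),
        "kin": kin.kinematic_record(recs, hinge),
        "hinge": hinge,
        "cc": cc,
    }


def mirror_landmarks(lm: cranio.LandmarkSet) -> cranio.LandmarkSet:
    """Reflect a landmark set through the midsagittal plane, swapping the
    side labels so the result is again a valid (mirror-image) subject."""

    def flip(name: str) -> str:
        if name.endswith("_L"):
            return name[:-2] + "_R"
        if name.endswith("_R"):
            return name[:-2] + "_L"
        return {"PoR": "PoL", "PoL": "PoR"}.get(name, name)

    M = np.diag([1.0, -1.0, 1.0])
    points = {flip(k): M @ v for k, v in lm.points.items()}
    profiles = {(("right" if s == "left" else "left"), n): p @ M.T
                for (s, n), p in lm.profiles.items()}
    return cranio.LandmarkSet(points, profiles)
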