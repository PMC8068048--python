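"""End-to-end pipeline: per-subject measurement, deviated/non-deviated-side
reorganization, eligibility filtering, and the statistics stage with report
writers.

A subject contributes a head frame, the craniofacial and TMJ morphometric
records, and the kinematic record; all per-side values are then re-keyed to
the deviated side (DS, the side the menton points toward) and the
non-deviated side (NDS).  Subjects failing the inclusion criteria (menton
deviation > 3 mm, Pog-NPerp > 0, ANB < 0) are excluded with logged reasons
before the cohort table reaches the statistics stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, stats
from .cranio import (CranioRecord, LandmarkSet, build_head_frame,
                     craniofacial_params, eligibility)
from .errors import JawkitError
from .kinematics import (KinematicRecord, MotionRecording, estimate_hinge_axis,
                         kinematic_record)
from .synth import (EffectSpec, MotionConfig, SkullConfig, generate_all_motions,
                    generate_cohort, generate_skull)
from .tmj import TmjRecord, condylar_centers, tmj_record


@dataclass
class AnalysisOptions:
    """Tunable pipeline knobs (defaults are the package's study conditions)."""

    smoothing_window: int = 7          # frames; 0 = no smoothing (exact data)
    rotation_window: float = 10.0      # deg, hinge-phase selection
    gap_angle_deg: float = 30.0        # joint-space sector coverage gate
    alpha: float = 0.05
    n_components: int = 4
    kaiser_normalize: bool = True
    fdr: bool = False                  # Benjamini-Hochberg on correlation p's
    power_variables: tuple = ("AES", "PCPL", "NCPL")
    factor_variables: tuple = tuple(stats.FACTOR_VARIABLES)
    target_power: float = 0.80


@dataclass
class SubjectRecord:
    """All measured parameters of one subject, organized DS/NDS."""

    subject_id: object
    cranio: CranioRecord
    tmj: TmjRecord
    kinematics: KinematicRecord
    eligible: bool
    exclusion_reasons: list[str]

    @property
    def deviated_side(self) -> str:
        return self.cranio.deviated_side

    def row(self) -> dict[str, float]:
        ds = self.deviated_side
        nds = "right" if ds == "left" else "left"
        out = {"menton_deviation": self.cranio.menton_deviation,
               "ANB": self.cranio.anb, "PogNPerp": self.cranio.pog_nperp}
        for label, side in (("DS", ds), ("NDS", nds)):
            for block in (self.cranio.side_values(side), self.tmj.side_values(side),
                          self.kinematics.side_values(side)):
                for k, v in block.items():
                    out[f"{k}_{label}"] = v
        return out


def measure_subject(subject_id, landmarks: LandmarkSet,
                    recordings: dict[str, MotionRecording],
                    options: AnalysisOptions | None = None) -> SubjectRecord:
    """Head frame -> morphometry -> hinge axis -> kinematics for one subject."""
    opt = options or AnalysisOptions()
    frame = build_head_frame(landmarks)
    cr = craniofacial_params(landmarks, frame)
    tr = tmj_record(landmarks, frame, gap_angle_deg=opt.gap_angle_deg)
    chs = landmarks.transformed(frame.to_chs)
    cc = condylar_centers(chs, build_head_frame(chs))
    hinge = estimate_hinge_axis(recordings["open_close"], condylar_centers=cc,
                                rotation_window=opt.rotation_window)
    kr = kinematic_record(recordings, hinge, smoothing_window=opt.smoothing_window)
    ok, reasons = eligibility(cr)
    return SubjectRecord(subject_id, cr, tr, kr, ok, reasons)


def cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """Assemble eligible subjects into the DS/NDS cohort table."""
    rows = {r.subject_id: r.row() for r in records if r.eligible}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject"
    return df


@dataclass
class CohortAnalysis:
    paired: pd.DataFrame
    correlations: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    factors: dict[str, "stats.FactorModel"]
    power: pd.DataFrame


def analyze_cohort(table: pd.DataFrame, options: AnalysisOptions | None = None
                   ) -> CohortAnalysis:
    """The statistics stage on a DS/NDS cohort table.

    Paired DS-vs-NDS t-tests on the full variable vocabulary; Pearson
    correlation of the TMJ-functional variables against the craniofacial and
    TMJ-morphometric variables per side; PCA with Varimax rotation per side;
    and paired-design power analysis on the representative variables.
    """
    opt = options or AnalysisOptions()
    n = len(table)
    paired = stats.paired_compare(table)
    paired_df = pd.DataFrame([{
        "variable": r.variable, "mean_DS": r.mean_ds, "sd_DS": r.sd_ds,
        "mean_NDS": r.mean_nds, "sd_NDS": r.sd_nds, "t": r.t, "p": r.p,
        "normality_p": r.normality_p} for r in paired]).set_index("variable")

    row_vars = [v for v in stats.CM_VARIABLES + stats.TM_VARIABLES
                if f"{v}_DS" in table.columns]
    col_vars = [v for v in stats.TF_VARIABLES if f"{v}_DS" in table.columns]
    correlations = {}
    for side in ("DS", "NDS"):
        r_mat, p_mat = stats.correlation_table(table, row_vars, col_vars, side)
        if opt.fdr:
            adj = stats.benjamini_hochberg(p_mat.to_numpy().ravel())
            p_mat = pd.DataFrame(adj.reshape(p_mat.shape), index=p_mat.index,
                                 columns=p_mat.columns)
        correlations[side] = (r_mat, p_mat)

    factors = {}
    for side in ("DS", "NDS"):
        cols = [f"{v}_{side}" for v in opt.factor_variables if f"{v}_{side}" in table.columns]
        X = table[cols].copy()
        X.columns = [c[: -len(side) - 1] for c in cols]
        model = stats.pca_loadings(X, k=opt.n_components)
        factors[side] = stats.rotate_factors(model, kaiser_normalize=opt.kaiser_normalize)

    power_rows = []
    for var in opt.power_variables:
        diff = table[f"{var}_DS"] - table[f"{var}_NDS"]
        dz = abs(float(diff.mean() / diff.std(ddof=1)))
        power_rows.append({
            "variable": var, "effect_size_dz": dz,
            "power_at_n": stats.power_paired_t(dz, n, opt.alpha),
            "n": n,
            "min_n_for_target": stats.min_n_paired_t(dz, opt.target_power, opt.alpha)})
    power_df = pd.DataFrame(power_rows).set_index("variable")
    return CohortAnalysis(paired_df, correlations, factors, power_df)


def write_reports(analysis: CohortAnalysis, table: pd.DataFrame, outdir,
                  manifest: dict | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "cohort_table.csv")
    analysis.paired.to_csv(out / "paired_comparison.csv")
    for side, (r_mat, p_mat) in analysis.correlations.items():
        r_mat.to_csv(out / f"correlation_r_{side}.csv")
        p_mat.to_csv(out / f"correlation_p_{side}.csv")
    for side, model in analysis.factors.items():
        model.loadings.to_csv(out / f"factor_loadings_{side}.csv")
    analysis.power.to_csv(out / "power_analysis.csv")
    if manifest is not None:
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic cohort mode or file mode)."""

    seed: int = 0
    n_subjects: int = 30
    marker_noise_sd: float = 0.05
    input_dir: str | None = None       # file mode: per-subject directories
    output_dir: str = "jawkit_out"
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        opts = AnalysisOptions(**d.pop("options", {}))
        cfg = PipelineConfig(**{k: v for k, v in d.items() if k != "options"})
        cfg.options = opts
        return cfg


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, CohortAnalysis]:
    """Generate-or-load, measure, filter, analyze, and write reports.

    Deterministic for a fixed seed.  Per-subject measurement failures are
    collected and reported, not fatal; only configuration errors abort.
    """
    records = []
    failures = {}
    if config.input_dir is None:
        subjects, _ = generate_cohort(config.n_subjects, seed=config.seed,
                                      marker_noise_sd=config.marker_noise_sd)
        for spec in subjects:
            sid = spec.subject_id
            try:
                lm, _ = generate_skull(spec.skull, seed=config.seed * 1009 + sid,
                                       world_pose="random")
                recs, _ = generate_all_motions(lm, spec.motion,
                                               seed=config.seed * 9176 + sid)
                records.append(measure_subject(sid, lm, recs, config.options))
            except JawkitError as e:
                failures[sid] = str(e)
    else:
        from . import io as jio
        root = Path(config.input_dir)
        for subdir in sorted(p for p in root.iterdir() if p.is_dir()):
            sid = subdir.name
            try:
                lm = jio.read_landmarks(subdir / "landmarks.csv", subdir / "profiles.csv")
                recs = {}
                for mv in ("open_close", "protrusion", "laterotrusion_left",
                           "laterotrusion_right"):
                    recs[mv] = jio.read_trajectory(subdir / f"{mv}.csv")
                records.append(measure_subject(sid, lm, recs, config.options))
            except JawkitError as e:
                failures[sid] = str(e)
    table = cohort_table(records)
    if len(table) < 3:
        raise JawkitError(f"fewer than 3 eligible subjects (failures: {failures})")
    analysis = analyze_cohort(table, config.options)
    manifest = {
        "jawkit_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()).hexdigest(),
        "n_measured": len(records),
        "n_eligible": int(len(table)),
        "excluded": {r.subject_id: r.exclusion_reasons
                     for r in records if not r.eligible},
        "failures": failures,
    }
    write_reports(analysis, table, config.output_dir, manifest)
    return table, analysis
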