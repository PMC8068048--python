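# Methods

This note documents the measurement models, the synthetic-data generator, the
statistical stage, and the numerical choices behind `jawkit`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reference geometry and the canonical head system

All measurements are defined relative to three mutually orthogonal reference
planes constructed from bony landmarks:

* **FH** (Frankfurt horizontal): through both porions and the left orbitale;
* **MSR** (midsagittal reference): perpendicular to FH, through nasion and
  basion;
* **coronal reference**: perpendicular to both, through basion.

Every subject is re-expressed in the canonical head system (CHS) these planes
induce — FH = {z = 0} with +z superior, MSR = {y = 0} with +y toward the
patient's left, coronal = {x = 0} with +x anterior — so each "frontal /
sagittal / axial view" measurement becomes a coordinate-plane projection, and
all reported values are invariant under rigid motion of the input
coordinates (verified by property tests under random world poses).

Orientation is resolved from landmark identity (right porion → left porion
defines +y), not from data heuristics.

## Morphometric measurements

**Craniofacial (per side).** Maxillary height (MxH) is the unsigned distance
from FH to the first-molar central fossa; ramal height (RH) the 3D
condyle-top-to-gonion distance; mandibular body length (BL) the
menton-gonion distance in axial projection; menton deviation the signed y of
menton in CHS (+ = left), with the deviated side (DS) the side menton points
toward. The frontal and lateral ramal inclinations (FRI, LRI) are angles of
the lateral/posterior ramus border — supplied as explicit two-point landmark
pairs, since border extraction belongs to the imaging workflow, not to this
package — against the FH trace in the frontal and sagittal projections.
They are reported in (0, 180) as the angle between the inferior-to-superior
border direction and the ray pointing laterally (FRI) or anteriorly (LRI),
preserving the acute/obtuse distinction rather than folding to [0, 90],
because clinically meaningful values straddle 90 degrees.

ANB and the pogonion-to-nasion-perpendicular distance are computed in the
sagittal projection with the N-perpendicular taken as the vertical line
through nasion; eligibility requires |menton deviation| > 3 mm (strict),
Pog–NPerp > 0 and ANB < 0.

**TMJ (per side).** The condylar center (CC) is found in the axial
projection at pole level (the mid-z of the medial/lateral poles) as the
intersection of the supporting lines of the largest lateromedial chord and
the largest anteroposterior chord of the outline polygon (equivalent to a
brute-force search over vertex pairs; tested against one). Extracapsular
posture (APCP, TCP, VCP) are the unsigned distances of CC to the coronal,
midsagittal and FH planes respectively — the assignment consistent with TCP
being about half the intercondylar width. Intracapsular spaces: SJS is the
vertical gap between the condylar highest point and the FH-parallel tangent
at the fossa roof; AJS/PJS (MJS/LJS) are minimal distances from the
anterior-/posterior-most (medial-/lateral-most) outline point to the
corresponding fossa wall profile in the sagittal (coronal) projection. The
minimal-gap reading was chosen over tangent-perpendicular distances; for the
straight or gently curved wall profiles considered here the two coincide at
the perpendicular foot. A `ProfileGapError` is raised when the nearest wall
point is a profile *endpoint* lying more than 30° (configurable) off the
measurement direction — an interior perpendicular foot always passes; the
gate detects profiles that do not cover the measured sector rather than
penalizing steep walls. The axial condylar angle (ACA) is the magnitude of
the pole-line angle to the pure-transverse direction, with the sign (+ =
medial pole posterior) stored separately. Eminence steepness (AES, PES, MES,
LES) are angles of total-least-squares lines through the projected wall
profiles versus FH; total least squares keeps the fit rotation-invariant.

## Kinematics

Per-frame mandibular poses come from least-squares rigid registration
(Kabsch) of the four markers against the first frame. The terminal hinge
axis is estimated from the opening recording: the initial contiguous frame
set whose frame-0-relative rotation stays within `rotation_window` (default
10°) and whose screw-axis pitch stays within 0.3 mm is the hinge phase
(the pitch gate requires two consecutive violations, so one noisy frame
cannot truncate the phase); the axis is then the weighted least-squares
common screw axis over all sufficiently separated *frame pairs* within the
phase, weighted by the squared pair rotation angle. Pairwise relative poses
matter: a frame-0-only decomposition inherits the reference frame's marker
noise as a common axis bias amplified by 1/angle, whereas pairs decorrelate
it. Condylar reference points are the projections of the measured condylar
centers onto the axis; the axis-horizontal plane contains the axis with
normal equal to head-vertical projected orthogonal to it, and all paths are
re-expressed with that plane as {z = 0}, +x anterior.

Dynamic parameters follow axiographic convention: path length is the
cumulative chord length of the monotone leg from the first frame to the
frame of maximal displacement (arc length, not straight-line excursion — a
fixed-excursion variant is a one-line change in `path_length`); SCI/TCI come
from total-least-squares lines through the sagittal/axial projections of the
protrusive leg (a fixed-chord alternative is exposed as
`inclination chord` via the path slicing, not enabled by default); the
Bennett angle is the axial angle of the chord to the point at exactly 1 mm
of cumulative path length (linear interpolation); NCPL/BA/NIPL from a
laterotrusion toward side W are assigned to the contralateral (non-working)
side. Optional centered moving-average smoothing (odd window, edge-
shrinking) is off by default so noiseless analyses are exact; the pipeline
default for noisy recordings is a 7-frame window at 30 Hz. The Bennett
chord is far more noise-sensitive than the path integrals, and the early
non-working path is straight — so smoothing it harder is bias-free; the
Bennett window defaults to 4x the general one.

## Synthetic subjects

The generator is a first-class module, not a fixture factory. Skulls are
stylized landmark/polyline models laid out directly in CHS and then moved by
a random world pose: every configured parameter is encoded so that the
measurement modules recover it **exactly** (machine precision; the
acceptance suite asserts 1e-6 over 100 random configurations). Condylar
outlines are 32-vertex ellipses (semi-axes 10 x 7 mm) rotated to the
configured ACA; fossa walls are straight 7-point profiles placed at the
configured perpendicular gap from the same outline-vertex prominences the
measurement uses; ramus borders encode the configured inclinations in the
relevant projections.

Motion recordings are rigid-body constructions. A rigid mandible cannot
realize two arbitrary independent condylar trajectories: with one straight
condylar path prescribed and the contralateral descent angle fixed, the
fixed intercondylar distance confines the contralateral extent to a conic
section. The generator prescribes the larger-extent side exactly and solves
the contralateral direction's small free azimuth so that its *extent* is
exact as well; the contralateral transverse inclination is therefore a
*derived* quantity (TCI on the coupled side can differ from the request by
a few degrees), and when rigidity caps the reachable extent the closest
realizable trajectory is generated. The incisal path length is met by
solving the free spin about the moving intercondylar axis, again
floor-limited by the yaw the non-working excursion imposes (realized NIPL
tends to sit slightly above a request far below that floor). **Ground truth
is always the parameter value computed from the analytic noiseless
trajectories with the same parameter definitions the measurement stage
uses** — so zero-noise recovery tests the estimation machinery (pose
registration, axis estimation, frame construction, path reconstruction),
while the parameter definitions themselves are tested separately against
closed-form and resampling oracles.

Opening starts with a pure-rotation terminal-hinge phase (first 10° of a
32° opening rotation, performed over the first 40 % of the opening time)
before the glide; the estimator is never told where the phase ends.
Movements go out, hold at maximum (half the out-leg duration — the
instructed pause at maximal excursion), and return; the hold also means
path smoothing cannot shave the turning point. Marker noise is isotropic
i.i.d. Gaussian per frame and coordinate (default 0.05 mm, the resolution
class of modern ultrasonic trackers); no systematic drift, soft-tissue
artifact, or outlier model is included, so noisy-recovery results bound
sensor noise only, not physiological artifacts. Markers sit bilaterally on
the ramus and anterior mandible so the condyles lie near the marker cloud —
pose extrapolation error is the dominant noise amplifier.

Cohorts draw per-subject parameter values from per-side Gaussians with the
interside means/SDs of the emulated study conditions, truncated to the
geometric invariants. Marginal tables never identify the DS/NDS pairing
correlation, so it is an explicit parameter (default 0.5). A shared latent
factor (loading 0.6) ties the deviated-side values of FRI, AES, MJS, ACA
and PCPL, reproducing the observed sign pattern of deviated-side
morpho-functional correlations. Interside sagittal-inclination differences
are capped at 20° — beyond that no rigid protrusion can carry both condylar
paths. Recording durations are 2.5 s (opening) and 1.5 s (excursions) at
30 Hz; these sizes keep full-cohort simulation studies fast while leaving
ample frames for the hinge phase.

## Statistics

* **Method error**: Dahlberg's formula, sqrt(Σd²/2n), over duplicate
  measurements.
* **Paired comparison**: Shapiro–Wilk p on the DS−NDS differences is
  reported but does not gate the paired t-test (a Wilcoxon fallback exists
  behind a flag, off by default). Identical sides return t = 0, p = 1;
  constant nonzero differences raise `DegenerateVariance`.
* **Correlation**: Pearson r with two-sided p from t = r·sqrt((n−2)/(1−r²));
  unadjusted by default (a Benjamini–Hochberg option exists, off by
  default, matching the presentation style of the emulated study design).
* **Factor analysis**: loadings are correlation-matrix eigenvectors scaled
  by sqrt(eigenvalue); the component count is fixed at 4 (the eigenvalue>1
  count is logged alongside — automatic scree-elbow detection is not
  reproducible and is deliberately absent). Varimax rotation uses Kaiser's
  sequential pairwise planar rotations with the closed-form optimal angle,
  Kaiser row normalization on by default, convergence when the criterion
  stalls below 1e-10 (orthogonality, hence communality preservation, is
  asserted on every call). Component sign is fixed by making each
  component's largest-magnitude loading positive; components are ordered by
  explained variance.
* **Power / sample size**: the paired (one-sample-on-differences)
  noncentral-t model — power = P(|T′| > t₁₋α/₂,ₙ₋₁) with noncentrality
  dz·√n — with exact increment-by-one search for the minimal n. This model
  reproduces the published minimal sample sizes (20, 10, 12) exactly; the
  published power percentages correspond to this model evaluated at n = 28,
  not at the stated n = 30 (all three match n = 28 to the printed
  precision, a reconstruction the acceptance script reports as such). The
  far lower tail of scipy's noncentral-t is clamped to zero where it
  underflows to NaN at large noncentrality.

## Problem sizes and tolerances

Acceptance-level studies use 100 skulls for the round-trip check, 50 seeded
simulations at 0.05 mm noise for kinematic recovery, 2000 cohorts for
type-I/power calibration, and 200 cohorts of 30 subjects for the
interside-effect emulation — sizes chosen so the complete study battery
runs in minutes on one core. Geometric constructions use 1e-9 unit/plane
tolerances, 1 mm minimum condylar width, a 1° screw-axis conditioning
floor, and 1e-12 root tolerances in the generator's azimuth solves.

## Known limitations

* The skull template is stylized; passing round-trip tests demonstrates the
  measurement pipeline's correctness on geometry that satisfies the
  measurement definitions exactly, not robustness to segmentation error,
  outline irregularity beyond convex perturbations, or landmark placement
  variability.
* Kinematic noise is sensor-like only; mandibular flexure, clutch slip and
  soft-tissue artifact are out of scope.
* TCI on the rigidly-coupled side and NIPL below its linkage floor are
  emulated approximately (documented above); cohort-level detection checks
  therefore target FRI, AES, PCPL and NCPL, whose generation is exact.
* Real axiograph vendor formats are not parsed; recordings enter through
  the documented CSV dialect.
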