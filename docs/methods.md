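# Methods

## Scope and data model

The package analyzes navel-relative 3D keypoint time series of a subject
walking two laps of a 1-m-diameter circle in each direction, captured at a
nominal 30 fps by a markerless monocular pose estimator.  The 24 canonical
keypoints, their per-sample confidence ("AI score") in [0, 1] and the CSV
interchange dialect are defined in `gaitplane.keypoints` and `gaitplane.io`.
The real capture app's export schema is unpublished; the dialect here
(`frame,time,<name>_x,<name>_y,<name>_z,<name>_score`, '#'-prefixed
metadata lines, empty cells for absent samples) is this package's own
deterministic stand-in, shared by parser and simulator.  Only one position
channel is stored; raw versus low-pass-filtered channels of the original app
are not distinguished because nothing downstream depends on the distinction.

Samples with confidence below the threshold (default 0.7) are dropped
individually; frames are never deleted, but a frame missing any trunk
keypoint needed for the body frame (navel, both shoulders, both hips)
contributes nothing downstream and is counted in a skip report.  No
interpolation or gap-filling is performed — there is no principled imputation
rule for pose-estimator dropouts, and the downstream statistics (means,
covariances) tolerate missing frames naturally.

## Body-axis frames

Per frame: `UF` is the unit normal of the plane through the navel and both
shoulders, `DF` of the plane through the navel and both hips.  Normals of
three points have an arbitrary sign, so `UF` is oriented anteriorly by
agreement with the navel→nose direction when the nose is present (fallback:
the cross-product order shoulder_r × shoulder_l, which is anterior under the
y-up screen convention), and `DF` is aligned with `UF`.  The forward axis is
the mean of the two unit normals.  That mean is generally not orthogonal to
the downward axis `c` (navel → hip midpoint), so it is Gram–Schmidt
projected against `c` and renormalized; mutual orthogonality then holds to
machine precision rather than approximately.  The lateral axis is `c × f`
with its sign fixed so the labelled right-side keypoints have positive
lateral coordinate — this makes the "outward" sign convention of the shift
indices anatomically meaningful on both sides and under mirrored input.
Averaging the *unit* normals (rather than the raw cross products) was
chosen so neither girdle dominates when shoulder and hip spans differ;
with either choice the Gram–Schmidt step gives an exactly orthonormal frame.

Frames are computed per time point, not averaged over the recording: the
trunk rotates continuously along the circular path, and the chronological
per-keypoint scatter in body coordinates is exactly what the ellipses
summarize.

Degenerate geometry (collinear trunk triples, vanishing `UF + DF`,
coincident navel and hip midpoint) is detected with a relative tolerance of
1e-8 and skips the frame with a reason, never silently producing an invalid
frame.

## Normalization

Leg length = |navel−hip| + |hip−knee| + |knee−heel| per side, averaged over
sides and over all usable frames; upper-body length = |navel−neck| +
|neck−head| with neck = shoulder midpoint and head = ear midpoint.  Lengths
are measured in 3D, so the normalized 2D projections are invariant under
global rotation, translation and scaling of the input (verified to 1e-6 in
the tests).  Hips, knees, heels, toes and the navel are divided by the leg
length; head, face, shoulders and arms by the upper-body length.  Arm
keypoints are projected for completeness but enter no index.

## Tolerance ellipses

For a projected point cloud of size n ≥ 3 the tolerance ellipse at level p
uses the sample mean, the unbiased covariance S and radius
r = √(2·F⁻¹(p; 2, n−1)) — the convention of the standard R data-ellipse
routine, which the analysis settings mirror (level 0.75, uniform weights).
A chi-square radius √(χ²⁻¹(p; 2)) is selectable (`radius_family="chi2"`);
the two agree to 1e-3 by n ≈ 10⁶.  Semi-axes follow from the
eigen-decomposition of S; the tilt lies in (−π/2, π/2] with tilt = 0 as the
deterministic tie-break for circular scatter.  Rank-deficient scatter yields
a flagged degenerate ellipse (b = 0) rather than an exception, because a
perfectly collinear keypoint track is a legitimate (if extreme) input.
Default area convention is π·a·b over the semi-axes; the literal
full-axis-product reading (4·π·a·b) is available as a config option since
areas are only ever compared relatively.

## Gait indices

All indices are computed per side and combined as the arithmetic mean of the
defined sides, with per-side raw values always retained — the published
analysis never states its left/right aggregation, and the mean is the
symmetric, fully disclosed choice that lets users recompute any other.

- **Hip / knee angle range** (sagittal): the angle subtended at the
  proximal ellipse's center by the two major-axis endpoints of the distal
  keypoint's ellipse (knee for the hip index, heel for the knee index).
  A fully degenerate distal ellipse gives 0° with a warning; coincident
  centers give 180° naturally (opposite endpoint vectors).
- **Heel vertical amplitude** (sagittal, leg = 1): by default the heel
  ellipse's vertical extent 2·r·√S_yy, which is outlier-robust; the raw
  max − min of the y coordinates is available as `mode="raw"` because the
  published phrase "y-axis width of the heel plots" admits both readings.
- **Foot angle** (axial): angle between the per-side heel-ellipse-center →
  toe-ellipse-center vectors (outward rotation of the feet).
- **Outward shifts** (axial, leg = 1): with the lateral coordinate positive
  toward the labelled right side, each side's outward sign is +1 (right) or
  −1 (left).  Toe shift = outward offset of the toe center from the heel
  center; heel shift = heel center from the hip center; leg shift is
  *defined* as their sum, so leg ≡ heel + toe holds exactly, per side and
  combined.  Negative values mean "inward"; the published heel-shift cutoff
  is itself negative (−0.08) because heels normally sit inside the hip
  joints.

Cutoff flags use strict inequalities in the published directions; a value
exactly at a cutoff raises no flag, and an undefined index yields an absent
flag rather than `False`.

## Screening metrics

Thresholding is strict in the stated direction; undefined values are
excluded with a logged count.  The odds ratio uses the Woolf logit 95% CI
with the Haldane–Anscombe +0.5 correction (flagged) on empty cells; the AUC
uses the Mann–Whitney rank formulation with tie correction and a DeLong 95%
CI (a method choice made here — the original analysis reports AUC CIs
without naming a method).  Ground-truth labels are taken as given in the
cohort manifest.  The identity OR = [sens/(1−sens)]·[spec/(1−spec)] is
exposed separately because it lets a published
sensitivity/specificity/odds-ratio triple be checked for internal
consistency without the underlying data.

## Synthetic gait simulator

The simulator emulates the measurement protocol, not a biomechanical
muscle model.  The pelvis advances along the circle at cadence·step_length/60
m/s; feet alternate 50%-duty stance/swing; a swinging heel advances one
stride with a cycloidal horizontal profile (zero velocity at contact) and a
half-sine vertical profile peaking at `step_height`; knees come from exact
two-link inverse kinematics; the upper body rides rigidly with lateral sway
toward the stance leg and a small double-frequency vertical bounce; arms are
static body-frame offsets.  Confidence scores are Beta(mean 0.88,
concentration 12) with 2% sub-threshold dropout to exercise the filter.
Everything is driven by one seeded generator: a fixed seed fixes the full
simulate → write → read → analyze chain.

Kinematic defaults (engineering choices, config not claims): cadence
100 steps/min, step length 0.60 m, stance width 0.07 m, thigh and shank
0.45 m, foot 0.20 m, hip-joint half-span 0.14 m, trunk sway 0.02 m, noise
SD 3 mm.  `step_height` — the maximum heel rise — defaults to 0.15 m: peak
heel elevation in normal adult gait is of order 0.15–0.25 m (the heel rises
steeply at toe-off even though mid-swing *toe* clearance is only a few
centimetres), and a heel that never leaves 0.05 m would itself register as
shuffling under the 0.1 leg-normalized amplitude cutoff.  Standing hip
height is 0.90 of the taut-leg maximum (slightly flexed knees), which keeps
the swing-leg hip–heel distance inside thigh+shank even when the heel stays
on the ground.  Presets: shuffling = step height ÷ 10; short-stepped = step
length ÷ 2.5; wide-based = stance width × 3 with foot rotation 20° and toe
outward offset 0.16 m.  With these defaults the normal preset clears every
published cutoff and each pathological preset crosses its matching cutoff
(heel amplitude for shuffling, knee angle range for short-stepped, leg
outward shift for wide-based) with a comfortable margin — which is the
design goal of the presets, since no quantitative kinematics of the
original acted gaits are available.  Cohort generation applies lognormal
between-subject jitter (σ = 0.06) to the kinematic fields and linearly
interpolates case parameters toward the preset by an effect-size scalar.

What the simulator does *not* model: perspective and camera motion (the
pipeline consumes body-relative data, so a camera model would cancel),
pose-estimator bias and structured outliers (noise is isotropic Gaussian),
stance-phase foot rolling, arm swing, double support, and the freezing /
festinating / spastic / ataxic patterns for which no quantitative definition
exists.  Passing tests therefore demonstrate correctness of the geometry and
statistics and plausibility of the index responses — not clinical
performance on real recordings, which are not publicly available.

## Numerical and design details

- Coordinates round-trip the CSV dialect at 9 decimals (1e-9), scores at 6.
- A recording mixing both walking directions carries `direction: unknown`;
  no index depends on the split, whose halves are balanced to ±1 frame.
- Stride plausibility is asserted along the walking path (arc length): on a
  1-m circle a 1.2-m stride's chord is ~22% shorter than its arc, and
  path-length is the conventional stride measure on curved walking.
- Problem sizes in the test suite (10,000-point calibration draws, 30+30
  cohorts per preset, one 200+200 null cohort) were chosen so Monte-Carlo
  error is small against the asserted tolerances while the whole suite stays
  interactive.
- Coronal-plane projections are computed and exportable, but no coronal
  index is defined (knee/ankle flexion is sagittal; foot geometry is clearer
  axially).
- Per-direction lap splitting, ground-referenced quantities (stance/swing
  segmentation, floor clearance) and temporal gait parameters are out of
  scope; cutoff optimization is deliberately absent — cutoffs are inputs.

## Known limitations

Labels in cohort manifests are treated as ground truth although clinical
gait-feature ratings are themselves subjective; the simulator's pathological
presets are stylized extremes, not patient kinematics; and the tolerance
ellipse assumes approximately bivariate-normal scatter, which multi-modal
keypoint tracks (e.g. a bimodal heel height distribution) only approximate —
the ellipse-based amplitude is then a dispersion summary rather than a
literal range, which is why the raw-range mode exists.
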