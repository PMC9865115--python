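# gaitplane

Quantitative gait-feature assessment from markerless full-body motion
capture.  A smartphone pose-estimation app records 24 anatomical keypoints
per video frame as navel-relative 3D coordinates while the subject walks two
laps of a 1-m circle, clockwise then counterclockwise.  `gaitplane` turns
those recordings into body-referenced 2D kinematic summaries and screens
them for three pathological gait features — shuffling (diminished step
height), short-stepped (reduced stride length) and wide-based (widened foot
placement) — which are hallmarks of idiopathic normal pressure hydrocephalus
and parkinsonian gait but are normally rated only subjectively.

Because the walk is circular and ground-referenced coordinates are
unavailable, all quantities are defined relative to the subject's own body
axes and segment lengths, making them invariant to camera pose, subject
position and body size.

## Method

**Body-axis frames.** For each frame, with navel `o`, shoulders and hips:

- `UF` = unit normal of the plane (navel, shoulder_r, shoulder_l), oriented
  anteriorly; `DF` likewise for the hips;
- forward `f` = (UF + DF)/2, Gram–Schmidt-orthogonalized against
- down `c` = unit(hip midpoint − navel);
- lateral `n` = c × f, sign fixed toward the subject's labelled right,

so that f·c = f·n = n·c = 0.  Keypoints are orthogonally projected onto the
sagittal (x = f, y = −c), coronal (x = n, y = −c) and axial (x = n, y = f)
planes through the navel, then divided by the total leg length (navel → hip
→ knee → heel, side- and frame-averaged) for lower-limb points or the
upper-body length for head/trunk points, so that leg = 1 defines the unit.

**Tolerance ellipses.** Each keypoint's projected scatter {xᵢ} is summarized
by its 75% bivariate-normal tolerance ellipse
`(x − m)ᵀ S⁻¹ (x − m) ≤ r²`, `r = √(2·F⁻¹(0.75; 2, n−1))`, with mean m and
unbiased covariance S; semi-axes a = r√λ₁ ≥ b = r√λ₂ from the
eigen-decomposition of S.

**Gait indices** (sagittal plane, leg = 1): the *hip angle range* is the
angle subtended at the hip-ellipse center by the knee ellipse's major-axis
endpoints; the *knee angle range* the same construction from the knee center
to the heel ellipse; the *heel vertical amplitude* is the heel ellipse's
vertical extent 2r√S_yy.  (Axial plane): the *foot angle* is the angle
between the right and left heel-center→toe-center vectors; the *heel*,
*toe* and *leg outward shifts* are signed lateral ellipse-center offsets,
positive away from the midline, with leg = heel + toe by construction.
Screening flags use the published cutoffs (strict inequalities): hip < 30°
and heel amplitude < 0.1 for shuffling, knee < 45° for shuffling and
short-stepped gait, heel shift > −0.08, toe shift > 0.18 and leg shift > 0.1
for wide-based gait.

**Cohort screening.** Per index and gait feature the package reports the
confusion counts at the cutoff, sensitivity, specificity, the odds ratio
(TP·TN)/(FN·FP) with a Woolf logit 95% CI (Haldane–Anscombe correction on
empty cells), and the ROC AUC via the Mann–Whitney statistic with a DeLong
95% CI.

**Simulator.** Real recordings of this protocol are not publicly deposited,
so the `simulate` module provides an articulated kinematic walker (circular
path, alternating stance/swing with cycloidal swing, two-link leg inverse
kinematics, Beta-distributed confidence scores, Gaussian keypoint noise)
emitting the same CSV dialect, with presets for all four gait patterns and
labeled case–control cohort generation.  See `docs/methods.md` for the
model, parameter defaults and limitations.

## Worked example

`python examples/simulate_and_analyze.py` simulates a normal and a shuffling
walk (seed 42) and prints:

```
normal gait — 377 frames, leg length 1.072 m
  hip angle range          70.2 deg (flag below 30)
  knee angle range         85.7 deg (flag below 45)
  heel vertical amplitude  0.176     (flag below 0.1, leg = 1)
  foot angle               46.8 deg (no cutoff)
  heel outward shift      -0.100    (flag above -0.08)
  toe outward shift       +0.058    (flag above 0.18)
  leg outward shift       -0.043    (flag above 0.1)
  flags raised: none

shuffling gait — 377 frames, leg length 1.072 m
  ...
  heel vertical amplitude  0.035     (flag below 0.1, leg = 1)
  flags raised: ['heel_vertical_amplitude']
```

The normal walk swings the legs through wide sagittal arcs (hip 70°, knee
86°) and lifts the heel through ~0.18 leg lengths, raising no flags; the
shuffling walk drags the feet, so the heel amplitude collapses to 0.035 and
the shuffling flag fires while the joint angle ranges stay near normal.
`examples/ellipse_calibration.py` and `examples/cohort_screening.py`
demonstrate ellipse coverage calibration and cohort-level ROC screening.

A thin CLI wraps the same pipeline:

```sh
gaitplane simulate shuffling --seed 3 --out walk.csv
gaitplane analyze walk.csv --out results/
gaitplane cohort manifest.csv --out results/
```

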