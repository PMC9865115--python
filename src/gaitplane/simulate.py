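"""Articulated kinematic gait simulator emulating the capture protocol.

A virtual walker follows a circle (default diameter 1 m) for a fixed number
of laps counterclockwise and then the same number clockwise, sampled at a
nominal 30 fps, emitting all 24 canonical keypoints as navel-relative 3D
coordinates with per-sample confidence scores — the same interchange format
the parser reads.

Kinematic model
---------------
* The pelvis center advances along the circle at ``cadence·step_length/60``
  m/s, with lateral trunk sway toward the stance leg and a small vertical
  bounce at twice the step frequency.
* Feet alternate 50%-duty stance/swing.  A planted heel is fixed on the
  ground; during swing it advances one stride (2·step_length) along the path
  with a cycloidal horizontal profile (zero velocity at the contacts) and a
  half-sine vertical profile peaking at ``step_height`` — the maximum heel
  rise.  Heels are offset laterally ±stance_width/2 from the pelvis path.
* The toe sits ``foot_length`` ahead of the heel, rotated outward by
  ``foot_rotation`` degrees, plus a ``toe_out_offset`` lateral outward
  offset.
* Knees are placed by exact two-link (thigh, shank) inverse kinematics
  between hip and heel, bending forward; thigh and shank lengths are rigid
  by construction.
* The upper body (head, ears, eyes, nose, shoulders) rides rigidly above the
  pelvis; arms are static offsets in the body frame (they enter no index).
* Isotropic Gaussian noise (``noise_sd``) is added to every emitted
  coordinate; confidence scores are Beta-distributed with a configurable
  sub-threshold dropout rate.  A fixed seed fixes the full output stream.

Presets map the acted gait patterns onto the baseline: shuffling divides the
step height by 10, short-stepped divides the step length by 2.5, wide-based
triples the stance width and increases the outward toe offset and foot
rotation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Recording
from .keypoints import KEYPOINT_INDEX, KEYPOINT_NAMES

UP = np.array([0.0, 1.0, 0.0])

# invariant trunk geometry (metres); these never enter an index directly —
# everything downstream is normalized by measured segment lengths
NAVEL_LIFT = 0.10       # hip-line center -> navel
SHOULDER_LIFT = 0.35    # navel -> shoulder line (= neck center)
SHOULDER_HALF = 0.18
HEAD_LIFT = 0.12        # neck center -> head center
EAR_HALF = 0.08
PELVIS_BOUNCE = 0.015   # vertical pelvis oscillation amplitude
HIP_CLEARANCE = 0.90    # hip height as a fraction of the taut-leg maximum;
                        # walking with slightly flexed knees keeps the swing
                        # leg reachable even when the heel stays near the ground


class ParameterError(ValueError):
    """A gait parameter set is unphysical or unreachable."""


@dataclass
class GaitParams:
    """Parameters of one simulated walk (lengths in metres, angles degrees)."""

    cadence: float = 100.0        # steps/min (left+right)
    step_length: float = 0.60     # per-step advance; stride = 2x
    step_height: float = 0.15     # maximum heel rise during swing
    stance_width: float = 0.07    # lateral heel-to-heel separation
    foot_rotation: float = 10.0   # outward foot yaw, degrees
    toe_out_offset: float = 0.03  # extra lateral outward toe offset
    thigh: float = 0.45
    shank: float = 0.45
    foot_length: float = 0.20
    pelvis_half: float = 0.14     # hip-joint lateral offset from midline
    trunk_sway: float = 0.02      # lateral pelvis sway amplitude
    circle_diameter: float = 1.0
    laps_per_direction: int = 2
    fps: float = 30.0
    noise_sd: float = 0.003
    score_mean: float = 0.88      # Beta confidence mean
    score_concentration: float = 12.0
    dropout_rate: float = 0.02    # probability of a sub-threshold score
    seed: int = 0

    def validate(self) -> None:
        for name in ("cadence", "step_length", "step_height", "stance_width",
                     "thigh", "shank", "foot_length", "pelvis_half",
                     "circle_diameter", "fps"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.laps_per_direction < 1:
            raise ParameterError("laps_per_direction must be >= 1")
        if self.noise_sd < 0 or self.trunk_sway < 0 or self.toe_out_offset < 0:
            raise ParameterError("noise_sd, trunk_sway, toe_out_offset must be >= 0")
        if not 0.0 < self.score_mean < 1.0:
            raise ParameterError("score_mean must lie in (0, 1)")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ParameterError("dropout_rate must lie in [0, 1]")
        reach = self.thigh + self.shank
        if self.step_length / 2.0 >= reach:
            raise ParameterError(
                f"step_length {self.step_length} exceeds leg reach: "
                f"step_length/2 must stay below thigh+shank = {reach}"
            )

    @property
    def speed(self) -> float:
        """Forward speed along the path, m/s."""
        return self.cadence * self.step_length / 60.0

    @property
    def step_period(self) -> float:
        """Seconds between successive (alternating-foot) heel strikes."""
        return 60.0 / self.cadence

    @property
    def hip_height(self) -> float:
        """Standing hip height chosen so the extended leg stays reachable."""
        reach = self.thigh + self.shank
        return HIP_CLEARANCE * math.sqrt(reach**2 - (self.step_length / 2.0) ** 2)

    def duration(self) -> float:
        """Closed-form total walk time: both directions at constant speed."""
        arc = math.pi * self.circle_diameter * self.laps_per_direction
        return 2.0 * arc / self.speed


PRESET_NAMES = ("normal", "shuffling", "short_stepped", "wide_based")

_BASE = GaitParams()
_PRESET_OVERRIDES: dict[str, dict[str, float]] = {
    "normal": {},
    "shuffling": {"step_height": _BASE.step_height / 10.0},
    "short_stepped": {"step_length": _BASE.step_length / 2.5},
    "wide_based": {"stance_width": _BASE.stance_width * 3.0,
                   "toe_out_offset": 0.16, "foot_rotation": 20.0},
}

#: Kinematic fields interpolated by the cohort effect-size scalar.
_EFFECT_FIELDS = ("cadence", "step_length", "step_height", "stance_width",
                  "foot_rotation", "toe_out_offset", "trunk_sway")


def preset(name: str, **overrides) -> GaitParams:
    """Named parameter presets for the four gait patterns."""
    if name not in PRESET_NAMES:
        raise ParameterError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    params = dataclasses.replace(GaitParams(), **_PRESET_OVERRIDES[name])
    params = dataclasses.replace(params, **overrides)
    params.validate()
    return params


def blend_params(base: GaitParams, target: GaitParams, effect: float) -> GaitParams:
    """Linear interpolation of the kinematic fields: effect 0 -> base, 1 -> target."""
    changes = {f: getattr(base, f) + effect * (getattr(target, f) - getattr(base, f))
               for f in _EFFECT_FIELDS}
    return dataclasses.replace(base, **changes)


def _path_point(d: np.ndarray, radius: float, s_dir: float,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Position, heading and rightward unit vectors at travel distance d.

    The path runs counterclockwise (in the horizontal x–z plane, seen with y
    up) for the first ``s_dir`` metres, then retraces clockwise.  d may run
    slightly past either end (feet plant ahead of / behind the pelvis).
    """
    d = np.asarray(d, dtype=float)
    ang_end = s_dir / radius
    first = d < s_dir
    ang = np.where(first, d / radius, ang_end - (d - s_dir) / radius)
    pos = np.stack([radius * np.cos(ang), np.zeros_like(ang), radius * np.sin(ang)],
                   axis=-1)
    tangent = np.stack([-np.sin(ang), np.zeros_like(ang), np.cos(ang)], axis=-1)
    heading = np.where(first[..., None], tangent, -tangent)
    right = np.stack([-heading[..., 2], np.zeros_like(ang), heading[..., 0]], axis=-1)
    return pos, heading, right


def _two_link_ik(hip: np.ndarray, heel: np.ndarray, forward: np.ndarray,
                 thigh: float, shank: float) -> np.ndarray:
    """Knee position bending toward ``forward``; exact link lengths."""
    delta = heel - hip
    d = np.linalg.norm(delta, axis=-1)
    reach = thigh + shank
    if np.any(d > reach - 1e-12):
        worst = float(np.max(d))
        raise ParameterError(
            f"inverse kinematics target at {worst:.3f} m exceeds leg reach "
            f"thigh+shank = {reach:.3f} m (reduce step_length or raise cadence)"
        )
    e1 = delta / d[..., None]
    x = (thigh**2 - shank**2 + d**2) / (2.0 * d)
    y = np.sqrt(np.maximum(thigh**2 - x**2, 0.0))
    e2 = forward - np.einsum("...j,...j->...", forward, e1)[..., None] * e1
    norm = np.linalg.norm(e2, axis=-1, keepdims=True)
    # fall back to the vertical plane if the leg happens to align with heading
    fallback = UP - np.einsum("...j,j->...", e1, UP)[..., None] * e1
    fb_norm = np.linalg.norm(fallback, axis=-1, keepdims=True)
    small = norm < 1e-9
    e2 = np.where(small, fallback / np.maximum(fb_norm, 1e-300), e2 / np.maximum(norm, 1e-300))
    return hip + x[..., None] * e1 + y[..., None] * e2


def simulate_recording(params: GaitParams, subject_id: str = "sim") -> Recording:
    """Simulate one two-direction circular walk as a Recording."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    radius = params.circle_diameter / 2.0
    s_dir = math.pi * params.circle_diameter * params.laps_per_direction
    duration = params.duration()
    n_frames = math.ceil(duration * params.fps)
    t = np.arange(n_frames) / params.fps

    v = params.speed
    T = params.step_period
    stride = 2.0 * params.step_length

    # pelvis -------------------------------------------------------------
    pel_d = v * t
    base, heading, right = _path_point(pel_d, radius, s_dir)
    chi_r = t / (2.0 * T)  # right-foot cycle variable
    sway = params.trunk_sway * np.sin(2.0 * np.pi * chi_r)
    bounce = 0.5 * PELVIS_BOUNCE * (1.0 - np.cos(4.0 * np.pi * chi_r))
    hip_center = (base + (params.hip_height + bounce)[..., None] * UP
                  + sway[..., None] * right)

    world = np.empty((n_frames, len(KEYPOINT_NAMES), 3))

    def put(name: str, pos: np.ndarray) -> None:
        world[:, KEYPOINT_INDEX[name]] = pos

    put("hip_r", hip_center + params.pelvis_half * right)
    put("hip_l", hip_center - params.pelvis_half * right)

    navel = hip_center + NAVEL_LIFT * UP
    put("center", navel)
    neck = navel + SHOULDER_LIFT * UP
    put("shoulder_r", neck + SHOULDER_HALF * right)
    put("shoulder_l", neck - SHOULDER_HALF * right)
    head = neck + HEAD_LIFT * UP
    put("ear_r", head + EAR_HALF * right)
    put("ear_l", head - EAR_HALF * right)
    put("eye_r", head + 0.06 * heading + 0.031 * right + 0.02 * UP)
    put("eye_l", head + 0.06 * heading - 0.031 * right + 0.02 * UP)
    put("nose", head + 0.09 * heading - 0.02 * UP)

    # arms: static offsets in the body frame (excluded from every index)
    for side, sgn in (("r", 1.0), ("l", -1.0)):
        shoulder = neck + sgn * SHOULDER_HALF * right
        elbow = shoulder + sgn * 0.03 * right - 0.28 * UP + 0.02 * heading
        wrist = elbow + sgn * 0.02 * right - 0.24 * UP + 0.06 * heading
        put(f"elbow_{side}", elbow)
        put(f"wrist_{side}", wrist)
        put(f"thumb_{side}", wrist + 0.06 * heading + sgn * 0.015 * right)
        put(f"middle_finger_{side}", wrist + 0.09 * heading - 0.02 * UP)

    # feet and knees -----------------------------------------------------
    rot = math.radians(params.foot_rotation)
    for side, sgn, off in (("r", 1.0, 0.0), ("l", -1.0, 0.5)):
        chi = t / (2.0 * T) + off
        k = np.floor(chi)
        u = chi - k
        swing = u >= 0.5
        w = np.clip((u - 0.5) * 2.0, 0.0, 1.0)
        prog = np.where(swing, w - np.sin(2.0 * np.pi * w) / (2.0 * np.pi), 0.0)
        heel_d = stride * (k - off + prog) + params.step_length / 2.0
        heel_y = np.where(swing, params.step_height * np.sin(np.pi * w), 0.0)

        hpos, hheading, hright = _path_point(heel_d, radius, s_dir)
        heel = (hpos + sgn * (params.stance_width / 2.0) * hright
                + heel_y[..., None] * UP)
        put(f"heel_{side}", heel)

        foot_dir = math.cos(rot) * hheading + math.sin(rot) * sgn * hright
        toe = (heel + params.foot_length * foot_dir
               + params.toe_out_offset * sgn * hright)
        put(f"toe_{side}", toe)

        hip = world[:, KEYPOINT_INDEX[f"hip_{side}"]]
        put(f"knee_{side}", _two_link_ik(hip, heel, heading, params.thigh, params.shank))

    # emit navel-relative coordinates with noise and confidence scores ----
    rel = world - navel[:, None, :]
    if params.noise_sd > 0:
        rel = rel + rng.normal(0.0, params.noise_sd, size=rel.shape)
    a = params.score_mean * params.score_concentration
    b = (1.0 - params.score_mean) * params.score_concentration
    scores = rng.beta(a, b, size=(n_frames, len(KEYPOINT_NAMES)))
    dropped = rng.random(size=scores.shape) < params.dropout_rate
    scores = np.where(dropped, rng.uniform(0.0, 0.5, size=scores.shape), scores)

    return Recording(times=t, positions=rel, scores=scores, fps=params.fps,
                     direction="unknown", subject_id=subject_id)


def simulate_cohort(n_cases: int, n_controls: int, feature: str,
                    effect: float = 1.0, seed: int = 0,
                    jitter_sd: float = 0.06,
                    ) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a labeled case–control cohort for one gait feature.

    Controls follow the normal preset; cases follow the feature's preset
    scaled toward baseline by ``effect`` (0 = indistinguishable from
    controls, 1 = full preset).  Every subject receives multiplicative
    lognormal between-subject jitter (``jitter_sd`` on the log scale) on the
    kinematic fields.  Fully deterministic for a given seed.

    Returns the recordings and a labels table (subject_id + label_* columns).
    """
    if n_cases < 1 or n_controls < 1:
        raise ParameterError("n_cases and n_controls must be >= 1")
    if feature not in ("shuffling", "short_stepped", "wide_based"):
        raise ParameterError(f"unknown gait feature {feature!r}")
    base = preset("normal")
    target = preset(feature)
    case_params = blend_params(base, target, effect)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cases + n_controls)
    recordings: list[Recording] = []
    rows = []
    for i, child in enumerate(children):
        is_case = i < n_cases
        proto = case_params if is_case else base
        rng = np.random.default_rng(child)
        jitter = {f: getattr(proto, f) * rng.lognormal(0.0, jitter_sd)
                  for f in _EFFECT_FIELDS}
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = dataclasses.replace(proto, seed=sub_seed, **jitter)
        params.validate()
        subject_id = f"{'case' if is_case else 'ctrl'}{i:03d}"
        rec = simulate_recording(params, subject_id=subject_id)
        rec.labels = {feature: is_case}
        recordings.append(rec)
        rows.append({"subject_id": subject_id,
                     "label_shuffling": feature == "shuffling" and is_case,
                     "label_short_stepped": feature == "short_stepped" and is_case,
                     "label_wide_based": feature == "wide_based" and is_case})
    return recordings, pd.DataFrame(rows)
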