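"""The seven gait indices computed from tolerance ellipses on body planes.

Sagittal plane (forward–vertical, leg length = 1):

* hip angle range  — angle subtended at the hip-ellipse center by the two
  major-axis endpoints of the knee ellipse (per side, then averaged);
* knee angle range — the same construction with the knee center and heel
  ellipse;
* heel vertical amplitude — vertical extent of the heel scatter, either the
  heel ellipse's y-width (default, outlier-robust) or the raw max−min range.

Axial plane (lateral–forward, leg length = 1):

* foot angle — angle between the right and left heel-center → toe-center
  vectors (outward foot rotation);
* heel / toe / leg outward shifts — signed lateral offsets of ellipse
  centers, positive away from the midline: per side the toe shift is the toe
  center's lateral offset from the heel center, the heel shift the heel
  center's offset from the hip center, and the leg shift their sum (an exact
  identity by construction).

Screening cutoffs (flag direction is strict, boundary = no flag):
hip angle < 30° and heel amplitude < 0.1 flag shuffling, knee angle < 45°
flags shuffling and short-stepped gait, heel shift > −0.08, toe shift > 0.18
and leg shift > 0.1 flag wide-based gait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .body_frame import ProjectedTracks
from .ellipse import ToleranceEllipse, fit_or_none, major_axis_endpoints, y_width
from .keypoints import SIDES

_SIDE_SIGN = {"r": 1.0, "l": -1.0}


@dataclass(frozen=True)
class IndexValue:
    """A combined index value with its per-side raw values (NaN = undefined)."""

    value: float
    right: float = float("nan")
    left: float = float("nan")

    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


@dataclass(frozen=True)
class CutoffConfig:
    """Published screening cutoffs; flag fires strictly past the cutoff.

    Angle cutoffs are in degrees, the rest in leg-normalized units.
    """

    hip_angle: float = 30.0        # flag when below
    knee_angle: float = 45.0       # flag when below
    heel_amplitude: float = 0.1    # flag when below
    heel_shift: float = -0.08      # flag when above
    toe_shift: float = 0.18        # flag when above
    leg_shift: float = 0.1         # flag when above


@dataclass(frozen=True)
class GaitIndexSet:
    hip_angle_range: IndexValue
    knee_angle_range: IndexValue
    heel_vertical_amplitude: IndexValue
    foot_angle: IndexValue
    heel_outward_shift: IndexValue
    toe_outward_shift: IndexValue
    leg_outward_shift: IndexValue

    def to_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in ("hip_angle_range", "knee_angle_range", "heel_vertical_amplitude",
                     "foot_angle", "heel_outward_shift", "toe_outward_shift",
                     "leg_outward_shift"):
            iv: IndexValue = getattr(self, name)
            out[name] = iv.value
            out[f"{name}_r"] = iv.right
            out[f"{name}_l"] = iv.left
        return out


@dataclass(frozen=True)
class IndexReport:
    indices: GaitIndexSet
    flags: dict[str, bool] = field(default_factory=dict)
    level: float = 0.75
    amplitude_mode: str = "ellipse"
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)


def _mean_sides(right: float, left: float) -> float:
    vals = [v for v in (right, left) if np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def angle_between_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two 2D vectors in degrees ([0, 180]); NaN if either is zero."""
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return float("nan")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _ellipse(tracks: ProjectedTracks, plane: str, kp: str, level: float,
             ) -> ToleranceEllipse | None:
    return fit_or_none(tracks.points[plane].get(kp), level, what=f"{plane}/{kp}")


def _apex_angle(apex_e: ToleranceEllipse | None,
                distal_e: ToleranceEllipse | None) -> float:
    """Angle subtended at the apex ellipse center by the distal major-axis ends."""
    if apex_e is None or distal_e is None:
        return float("nan")
    if distal_e.degenerate and distal_e.a == 0.0:
        warnings.warn("distal ellipse fully degenerate; angle range set to 0",
                      stacklevel=2)
        return 0.0
    p1, p2 = major_axis_endpoints(distal_e)
    return angle_between_deg(p1 - apex_e.center, p2 - apex_e.center)


def hip_angle_range(tracks: ProjectedTracks, level: float = 0.75) -> IndexValue:
    """Sagittal angle range of the hip joint (degrees), per side and averaged."""
    vals = {}
    for s in SIDES:
        hip_e = _ellipse(tracks, "sagittal", f"hip_{s}", level)
        knee_e = _ellipse(tracks, "sagittal", f"knee_{s}", level)
        vals[s] = _apex_angle(hip_e, knee_e)
    return IndexValue(_mean_sides(vals["r"], vals["l"]), vals["r"], vals["l"])


def knee_angle_range(tracks: ProjectedTracks, level: float = 0.75) -> IndexValue:
    """Sagittal angle range of the knee joint (degrees), per side and averaged."""
    vals = {}
    for s in SIDES:
        knee_e = _ellipse(tracks, "sagittal", f"knee_{s}", level)
        heel_e = _ellipse(tracks, "sagittal", f"heel_{s}", level)
        vals[s] = _apex_angle(knee_e, heel_e)
    return IndexValue(_mean_sides(vals["r"], vals["l"]), vals["r"], vals["l"])


def heel_vertical_amplitude(tracks: ProjectedTracks, level: float = 0.75,
                            mode: str = "ellipse") -> IndexValue:
    """Leg-normalized vertical extent of the sagittal heel scatter.

    mode='ellipse' (default) uses the heel tolerance ellipse's y-width;
    mode='raw' uses the raw max−min of the y coordinates.
    """
    if mode not in ("ellipse", "raw"):
        raise ValueError(f"unknown amplitude mode {mode!r}")
    vals = {}
    for s in SIDES:
        pts = tracks.points["sagittal"].get(f"heel_{s}")
        if mode == "raw":
            vals[s] = (float(pts[:, 1].max() - pts[:, 1].min())
                       if pts is not None and len(pts) else float("nan"))
        else:
            e = _ellipse(tracks, "sagittal", f"heel_{s}", level)
            vals[s] = y_width(e) if e is not None else float("nan")
    return IndexValue(_mean_sides(vals["r"], vals["l"]), vals["r"], vals["l"])


def foot_angle(tracks: ProjectedTracks, level: float = 0.75) -> IndexValue:
    """Axial angle between the right and left heel-center → toe-center vectors."""
    vecs = {}
    for s in SIDES:
        heel_e = _ellipse(tracks, "axial", f"heel_{s}", level)
        toe_e = _ellipse(tracks, "axial", f"toe_{s}", level)
        vecs[s] = (toe_e.center - heel_e.center
                   if heel_e is not None and toe_e is not None else None)
    if vecs["r"] is None or vecs["l"] is None:
        return IndexValue(float("nan"))
    value = angle_between_deg(vecs["r"], vecs["l"])
    if not np.isfinite(value):
        warnings.warn("zero-length heel→toe vector; foot angle undefined", stacklevel=2)
    return IndexValue(value)


def outward_shifts(tracks: ProjectedTracks, level: float = 0.75,
                   ) -> tuple[IndexValue, IndexValue, IndexValue]:
    """(heel, toe, leg) outward shifts on the axial plane, positive = outward.

    The per-side leg shift is defined as heel + toe shift, so the identity
    ``leg = heel + toe`` holds exactly for the combined values as well.
    """
    heel_s, toe_s, leg_s = {}, {}, {}
    for s in SIDES:
        sign = _SIDE_SIGN[s]
        hip_e = _ellipse(tracks, "axial", f"hip_{s}", level)
        heel_e = _ellipse(tracks, "axial", f"heel_{s}", level)
        toe_e = _ellipse(tracks, "axial", f"toe_{s}", level)
        x_hip = hip_e.center[0] if hip_e is not None else float("nan")
        x_heel = heel_e.center[0] if heel_e is not None else float("nan")
        x_toe = toe_e.center[0] if toe_e is not None else float("nan")
        heel_s[s] = sign * (x_heel - x_hip)
        toe_s[s] = sign * (x_toe - x_heel)
        leg_s[s] = heel_s[s] + toe_s[s]
    heel = IndexValue(_mean_sides(heel_s["r"], heel_s["l"]), heel_s["r"], heel_s["l"])
    toe = IndexValue(_mean_sides(toe_s["r"], toe_s["l"]), toe_s["r"], toe_s["l"])
    leg = IndexValue(heel.value + toe.value, leg_s["r"], leg_s["l"])
    return heel, toe, leg


def flags_from_indices(idx: GaitIndexSet, cutoffs: CutoffConfig | None = None,
                       ) -> dict[str, bool]:
    """Strict-inequality cutoff flags; undefined indices are absent, not False."""
    c = cutoffs or CutoffConfig()
    rules = {
        "hip_angle_range": (idx.hip_angle_range.value, c.hip_angle, "below"),
        "knee_angle_range": (idx.knee_angle_range.value, c.knee_angle, "below"),
        "heel_vertical_amplitude": (idx.heel_vertical_amplitude.value,
                                    c.heel_amplitude, "below"),
        "heel_outward_shift": (idx.heel_outward_shift.value, c.heel_shift, "above"),
        "toe_outward_shift": (idx.toe_outward_shift.value, c.toe_shift, "above"),
        "leg_outward_shift": (idx.leg_outward_shift.value, c.leg_shift, "above"),
    }
    flags: dict[str, bool] = {}
    for name, (value, cut, direction) in rules.items():
        if not np.isfinite(value):
            continue
        flags[name] = bool(value < cut) if direction == "below" else bool(value > cut)
    return flags


def compute_indices(tracks: ProjectedTracks, level: float = 0.75,
                    cutoffs: CutoffConfig | None = None,
                    amplitude_mode: str = "ellipse") -> IndexReport:
    """All seven indices plus cutoff flags for one projected recording."""
    heel, toe, leg = outward_shifts(tracks, level)
    idx = GaitIndexSet(
        hip_angle_range=hip_angle_range(tracks, level),
        knee_angle_range=knee_angle_range(tracks, level),
        heel_vertical_amplitude=heel_vertical_amplitude(tracks, level, amplitude_mode),
        foot_angle=foot_angle(tracks, level),
        heel_outward_shift=heel,
        toe_outward_shift=toe,
        leg_outward_shift=leg,
    )
    cfg = cutoffs or CutoffConfig()
    return IndexReport(indices=idx, flags=flags_from_indices(idx, cfg), level=level,
                       amplitude_mode=amplitude_mode, cutoffs=cfg)
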