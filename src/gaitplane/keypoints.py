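"""Canonical keypoint vocabulary for full-body markerless capture.

The capture app estimates 24 named landmarks per video frame, expressed as
navel-relative 3D coordinates.  Everything downstream (body frames, plane
projection, indices) addresses keypoints by these names, in this order.
"""

from __future__ import annotations

#: The 24 canonical keypoint names, in on-disk column order.
KEYPOINT_NAMES: tuple[str, ...] = (
    "center",
    "nose",
    "ear_l",
    "ear_r",
    "eye_l",
    "eye_r",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "thumb_l",
    "thumb_r",
    "middle_finger_l",
    "middle_finger_r",
    "hip_l",
    "hip_r",
    "knee_l",
    "knee_r",
    "heel_l",
    "heel_r",
    "toe_l",
    "toe_r",
)

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

#: Lower-limb group: normalized by total leg length (leg = 1).  The trunk
#: center anchors the leg chain, so it is scaled with the legs.
LOWER_GROUP: frozenset[str] = frozenset(
    {"center", "hip_l", "hip_r", "knee_l", "knee_r", "heel_l", "heel_r", "toe_l", "toe_r"}
)

#: Head/trunk group: normalized by upper-body length (upper = 1).
UPPER_GROUP: frozenset[str] = frozenset(
    {"nose", "ear_l", "ear_r", "eye_l", "eye_r", "shoulder_l", "shoulder_r"}
)

#: Arm keypoints are projected for completeness but excluded from all gait
#: indices; they share the upper-body normalization.
ARM_GROUP: frozenset[str] = frozenset(
    {"elbow_l", "elbow_r", "wrist_l", "wrist_r", "thumb_l", "thumb_r",
     "middle_finger_l", "middle_finger_r"}
)

#: Derived (computed, not measured) keypoints carried through projection:
#: head center = midpoint of the ears, neck center = midpoint of the shoulders.
DERIVED_NAMES: tuple[str, ...] = ("head_center", "neck_center")

SIDES: tuple[str, str] = ("r", "l")


def side_name(base: str, side: str) -> str:
    """Return the canonical name for a sided keypoint, e.g. ('hip', 'r') -> 'hip_r'."""
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return f"{base}_{side}"
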