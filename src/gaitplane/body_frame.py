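"""Per-frame body-axis frames and orthogonal plane projection.

For every video frame a body-fixed orthonormal frame is built from the trunk:

* ``UF`` — unit normal of the plane through the navel and both shoulders,
  oriented anteriorly (sign checked against the nose when present);
* ``DF`` — unit normal of the plane through the navel and both hip joints,
  oriented to agree with ``UF``;
* ``f``  — forward axis: the mean of the two unit normals, made exactly
  orthogonal to ``c`` by Gram–Schmidt;
* ``c``  — downward axis: unit vector from the navel to the hip midpoint;
* ``n``  — lateral axis: ``c × f`` with the sign fixed so that the labelled
  right-side keypoints have positive ``n`` coordinate.

Keypoints are orthogonally projected onto three body planes anchored at the
navel: sagittal (x = forward f, y = up −c), coronal (x = lateral n, y = up)
and axial (x = lateral n, y = forward f).  Projected coordinates are
dimensionless: lower-limb points are divided by the total leg length and
head/trunk points by the upper-body length, both measured in 3D and averaged
over frames, so the whole pipeline is invariant to global rigid motion and
scale of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Recording, RecordingValidationError, filter_by_score
from .keypoints import DERIVED_NAMES, KEYPOINT_INDEX, KEYPOINT_NAMES, LOWER_GROUP

PLANES = ("sagittal", "coronal", "axial")

_REL_TOL = 1e-8  # relative degeneracy tolerance for cross products / norms


class DegenerateFrameError(ValueError):
    """The trunk keypoints of a frame do not span a usable body frame."""


@dataclass(frozen=True)
class BodyFrame:
    """Origin (navel) plus the orthonormal forward/down/lateral axes."""

    origin: np.ndarray
    f: np.ndarray  # forward
    c: np.ndarray  # down
    n: np.ndarray  # lateral, toward the labelled right side


@dataclass(frozen=True)
class SegmentLengths:
    """3D segment lengths used as normalization denominators (leg, upper)."""

    leg: float
    upper: float


@dataclass
class ProjectedTracks:
    """Per-plane, per-keypoint 2D point clouds in normalized units.

    ``points[plane][keypoint]`` is an (m, 2) array; ``frames[keypoint]`` gives
    the source frame index of each point (shared across planes).
    """

    points: dict[str, dict[str, np.ndarray]]
    frames: dict[str, np.ndarray]
    lengths: SegmentLengths
    n_frames: int
    n_frames_used: int
    skip_reasons: dict[str, int] = field(default_factory=dict)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format export: columns plane, keypoint, frame, x, y."""
        rows = []
        for plane in PLANES:
            for kp, pts in self.points[plane].items():
                idx = self.frames[kp]
                for j in range(pts.shape[0]):
                    rows.append((plane, kp, int(idx[j]), pts[j, 0], pts[j, 1]))
        return pd.DataFrame(rows, columns=["plane", "keypoint", "frame", "x", "y"])


def _unit(v: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    norm = np.linalg.norm(v, axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = v / norm
    return u, norm[..., 0]


def _batch_frames(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                                  np.ndarray, np.ndarray, dict[str, int]]:
    """Vectorized frame construction.

    Returns (origin, f, c, n, valid, skip_reasons); rows with valid=False hold NaN.
    """
    idx = KEYPOINT_INDEX
    center = positions[:, idx["center"]]
    sr = positions[:, idx["shoulder_r"]]
    sl = positions[:, idx["shoulder_l"]]
    hr = positions[:, idx["hip_r"]]
    hl = positions[:, idx["hip_l"]]
    nose = positions[:, idx["nose"]]

    skip: dict[str, int] = {}
    required = np.stack([center, sr, sl, hr, hl], axis=1)
    have_req = np.all(np.isfinite(required), axis=(1, 2))
    skip["missing_trunk_keypoint"] = int(np.sum(~have_req))

    with np.errstate(invalid="ignore", divide="ignore"):
        a_s, b_s = sr - center, sl - center
        uf_raw = np.cross(a_s, b_s)
        uf_scale = np.linalg.norm(a_s, axis=1) * np.linalg.norm(b_s, axis=1)
        uf, uf_norm = _unit(uf_raw)
        ok_uf = uf_norm > _REL_TOL * np.maximum(uf_scale, 1e-300)

        # anterior orientation: agree with the nose when it is available
        nose_ok = np.all(np.isfinite(nose), axis=1)
        sgn = np.einsum("ij,ij->i", uf, np.where(nose_ok[:, None], nose - center, np.nan))
        flip = nose_ok & (sgn < 0)
        uf = np.where(flip[:, None], -uf, uf)

        a_h, b_h = hr - center, hl - center
        df_raw = np.cross(a_h, b_h)
        df_scale = np.linalg.norm(a_h, axis=1) * np.linalg.norm(b_h, axis=1)
        df, df_norm = _unit(df_raw)
        ok_df = df_norm > _REL_TOL * np.maximum(df_scale, 1e-300)
        flip_df = np.einsum("ij,ij->i", df, uf) < 0
        df = np.where(flip_df[:, None], -df, df)

        hip_mid = 0.5 * (hr + hl)
        c_raw = hip_mid - center
        c, c_norm = _unit(c_raw)
        body_scale = np.linalg.norm(sr - sl, axis=1) + np.linalg.norm(hr - hl, axis=1)
        ok_c = c_norm > _REL_TOL * np.maximum(body_scale, 1e-300)

        f_mean = 0.5 * (uf + df)
        f_gs = f_mean - np.einsum("ij,ij->i", f_mean, c)[:, None] * c
        f, f_norm = _unit(f_gs)
        ok_f = f_norm > _REL_TOL

        n_vec = np.cross(c, f)
        r_dir = (sr - sl) + (hr - hl)
        flip_n = np.einsum("ij,ij->i", n_vec, r_dir) < 0
        n_vec = np.where(flip_n[:, None], -n_vec, n_vec)

    ok_geom = ok_uf & ok_df & ok_c & ok_f
    skip["degenerate_geometry"] = int(np.sum(have_req & ~ok_geom))
    valid = have_req & ok_geom

    inv = ~valid
    for arr in (f, c, n_vec):
        arr[inv] = np.nan
    origin = np.where(valid[:, None], center, np.nan)
    return origin, f, c, n_vec, valid, skip


def compute_frame(positions: np.ndarray | dict[str, np.ndarray]) -> BodyFrame:
    """Build the body frame of a single frame.

    Parameters
    ----------
    positions : (24, 3) array ordered by ``KEYPOINT_NAMES``, or a mapping
        name -> 3-vector (missing names are treated as absent).

    Raises
    ------
    DegenerateFrameError
        If a required keypoint is missing or the trunk geometry is degenerate
        (e.g. collinear navel/shoulder triple).
    """
    if isinstance(positions, dict):
        arr = np.full((len(KEYPOINT_NAMES), 3), np.nan)
        for name, p in positions.items():
            arr[KEYPOINT_INDEX[name]] = np.asarray(p, dtype=float)
    else:
        arr = np.asarray(positions, dtype=float)
    origin, f, c, n_vec, valid, skip = _batch_frames(arr[None])
    if not valid[0]:
        reason = next((k for k, v in skip.items() if v), "degenerate_geometry")
        raise DegenerateFrameError(reason)
    return BodyFrame(origin=origin[0], f=f[0], c=c[0], n=n_vec[0])


def project_point(p: np.ndarray, bf: BodyFrame, plane: str) -> np.ndarray:
    """Orthogonally project a 3D point onto one body plane (2D result).

    sagittal -> (d·f, −d·c); coronal -> (d·n, −d·c); axial -> (d·n, d·f),
    with d = p − origin.
    """
    d = np.asarray(p, dtype=float) - bf.origin
    if plane == "sagittal":
        return np.array([d @ bf.f, -(d @ bf.c)])
    if plane == "coronal":
        return np.array([d @ bf.n, -(d @ bf.c)])
    if plane == "axial":
        return np.array([d @ bf.n, d @ bf.f])
    raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")


def segment_lengths(rec: Recording) -> SegmentLengths:
    """Mean 3D leg and upper-body lengths over all usable frames.

    Leg (per side): |center−hip| + |hip−knee| + |knee−heel|, averaged over
    sides and frames.  Upper body: |navel−neck| + |neck−head| with the neck
    center at the shoulder midpoint and the head center at the ear midpoint.
    """
    P = rec.positions
    idx = KEYPOINT_INDEX

    def dist(a: str, b: str) -> np.ndarray:
        return np.linalg.norm(P[:, idx[a]] - P[:, idx[b]], axis=1)

    legs = []
    for s in ("r", "l"):
        legs.append(dist("center", f"hip_{s}") + dist(f"hip_{s}", f"knee_{s}")
                    + dist(f"knee_{s}", f"heel_{s}"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames are fine
        leg_per_frame = np.nanmean(np.stack(legs), axis=0)

    neck = 0.5 * (P[:, idx["shoulder_r"]] + P[:, idx["shoulder_l"]])
    head = 0.5 * (P[:, idx["ear_r"]] + P[:, idx["ear_l"]])
    navel = P[:, idx["center"]]
    upper_per_frame = (np.linalg.norm(neck - navel, axis=1)
                       + np.linalg.norm(head - neck, axis=1))

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN mean -> NaN
        leg = float(np.nanmean(leg_per_frame))
        upper = float(np.nanmean(upper_per_frame))
    if not np.isfinite(leg) or leg <= 0:
        raise RecordingValidationError("no frame provides a usable leg length")
    if not np.isfinite(upper) or upper <= 0:
        raise RecordingValidationError("no frame provides a usable upper-body length")
    return SegmentLengths(leg=leg, upper=upper)


def project_recording(rec: Recording, score_threshold: float = 0.7,
                      include_derived: bool = True) -> ProjectedTracks:
    """Confidence-filter, build per-frame body frames, project and normalize.

    Frames whose trunk keypoints are missing or degenerate contribute nothing
    (counts reported in ``skip_reasons``).  Raises if fewer than two frames
    are usable, since no ellipse can be fitted downstream.
    """
    filtered = filter_by_score(rec, score_threshold)
    P = filtered.positions
    origin, f, c, n_vec, valid, skip = _batch_frames(P)
    n_used = int(valid.sum())
    if n_used < 2:
        raise RecordingValidationError(
            f"only {n_used} usable frame(s) after filtering; need >= 2"
        )
    lengths = segment_lengths(filtered)

    idx = KEYPOINT_INDEX
    names = list(KEYPOINT_NAMES)
    tracks3d = [P[:, idx[name]] for name in names]
    if include_derived:
        ear_pair = np.stack([P[:, idx["ear_r"]], P[:, idx["ear_l"]]])
        sh_pair = np.stack([P[:, idx["shoulder_r"]], P[:, idx["shoulder_l"]]])
        tracks3d.append(np.where(np.all(np.isfinite(ear_pair), axis=(0, 2))[:, None],
                                 ear_pair.mean(axis=0), np.nan))
        tracks3d.append(np.where(np.all(np.isfinite(sh_pair), axis=(0, 2))[:, None],
                                 sh_pair.mean(axis=0), np.nan))
        names += list(DERIVED_NAMES)

    scale = {name: lengths.leg if name in LOWER_GROUP else lengths.upper
             for name in names}  # derived head/neck fall to upper via default below
    for name in DERIVED_NAMES:
        scale[name] = lengths.upper

    points: dict[str, dict[str, np.ndarray]] = {plane: {} for plane in PLANES}
    frames: dict[str, np.ndarray] = {}
    frame_index = np.arange(rec.n_frames)
    for name, track in zip(names, tracks3d):
        mask = valid & np.all(np.isfinite(track), axis=1)
        if not np.any(mask):
            continue
        d = track[mask] - origin[mask]
        xf = np.einsum("ij,ij->i", d, f[mask])
        xc = np.einsum("ij,ij->i", d, c[mask])
        xn = np.einsum("ij,ij->i", d, n_vec[mask])
        s = scale[name]
        points["sagittal"][name] = np.column_stack([xf, -xc]) / s
        points["coronal"][name] = np.column_stack([xn, -xc]) / s
        points["axial"][name] = np.column_stack([xn, xf]) / s
        frames[name] = frame_index[mask]

    return ProjectedTracks(points=points, frames=frames, lengths=lengths,
                           n_frames=rec.n_frames, n_frames_used=n_used,
                           skip_reasons=skip)
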