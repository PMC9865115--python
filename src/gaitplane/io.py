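"""Reading, writing and confidence filtering of keypoint recordings.

On-disk interchange format (``gaitplane keypoint dialect v1``)
--------------------------------------------------------------
A UTF-8 CSV with '.' decimals, a few ``#``-prefixed metadata lines, one header
row, and one row per video frame::

    # gaitplane-dialect: v1
    # coordinate-convention: x=screen-right, y=screen-up, z=toward-camera, origin=navel
    # fps: 30.000000
    # direction: unknown
    # subject_id: s001
    frame,time,center_x,center_y,center_z,center_score,nose_x,...,toe_r_score

Columns are ``frame``, ``time`` (seconds, strictly increasing), then four
columns per canonical keypoint: ``<name>_x``, ``<name>_y``, ``<name>_z``,
``<name>_score``.  Coordinates are navel-relative (the app's convention) in
the recording's own length unit; the confidence score lies in [0, 1].  Empty
cells denote an absent sample, never zero.

The real capture app's export schema is not published; this dialect is the
package's own deterministic stand-in, shared by the simulator and the parser.

A cohort manifest is a CSV with columns
``subject_id,path,label_shuffling,label_short_stepped,label_wide_based``
(labels 0/1), paths relative to the manifest's directory or absolute.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .keypoints import KEYPOINT_NAMES

logger = logging.getLogger(__name__)

DIALECT_VERSION = "v1"
DIRECTIONS = ("clockwise", "counterclockwise", "unknown")

_COORD_FMT = "%.9f"   # round-trip coordinates to 1e-9
_SCORE_FMT = "%.6f"   # scores exact at 6 decimals
_TIME_FMT = "%.6f"

MANIFEST_LABEL_COLUMNS = (
    "label_shuffling",
    "label_short_stepped",
    "label_wide_based",
)


class FormatError(ValueError):
    """The file does not conform to the keypoint CSV dialect."""


class RecordingValidationError(ValueError):
    """The data violate a Recording invariant (e.g. non-monotone time)."""


def _expected_columns() -> list[str]:
    cols = ["frame", "time"]
    for name in KEYPOINT_NAMES:
        cols += [f"{name}_x", f"{name}_y", f"{name}_z", f"{name}_score"]
    return cols


@dataclass
class Recording:
    """A keypoint time series for one walk.

    Attributes
    ----------
    times : (n_frames,) float array, seconds, strictly increasing.
    positions : (n_frames, 24, 3) float array ordered by ``KEYPOINT_NAMES``;
        NaN rows mark absent samples.
    scores : (n_frames, 24) float array in [0, 1]; NaN marks absent.
    fps : nominal capture rate (frames/second).
    direction : 'clockwise' | 'counterclockwise' | 'unknown'.  A file holding
        both halves of the circular-walk protocol uses 'unknown'.
    subject_id : opaque label.
    labels : optional map gait-feature name -> bool ground truth.
    """

    times: np.ndarray
    positions: np.ndarray
    scores: np.ndarray
    fps: float = 30.0
    direction: str = "unknown"
    subject_id: str = ""
    labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        n = self.times.shape[0]
        if self.positions.shape != (n, len(KEYPOINT_NAMES), 3):
            raise RecordingValidationError(
                f"positions shape {self.positions.shape} != ({n}, 24, 3)"
            )
        if self.scores.shape != (n, len(KEYPOINT_NAMES)):
            raise RecordingValidationError(
                f"scores shape {self.scores.shape} != ({n}, 24)"
            )
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise RecordingValidationError("frame timestamps must be strictly increasing")
        if self.fps <= 0:
            raise RecordingValidationError("fps must be positive")
        if self.direction not in DIRECTIONS:
            raise RecordingValidationError(
                f"direction {self.direction!r} not in {DIRECTIONS}"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.scores < 0) | (self.scores > 1)
        if np.any(bad):
            raise RecordingValidationError("scores must lie in [0, 1]")
        # a sample missing any channel is absent altogether
        absent = np.any(~np.isfinite(self.positions), axis=2) | ~np.isfinite(self.scores)
        self.positions[absent] = np.nan
        self.scores[absent] = np.nan

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    def present_mask(self) -> np.ndarray:
        """(n_frames, 24) boolean mask of present samples."""
        return np.isfinite(self.scores)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the v1 dialect.

    Output is byte-stable for a given recording: floats use fixed formats
    (coordinates 9 decimals, scores 6), absent samples are empty cells.
    """
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# gaitplane-dialect: {DIALECT_VERSION}\n")
    buf.write(
        "# coordinate-convention: x=screen-right, y=screen-up, "
        "z=toward-camera, origin=navel\n"
    )
    buf.write(f"# fps: {rec.fps:.6f}\n")
    buf.write(f"# direction: {rec.direction}\n")
    buf.write(f"# subject_id: {rec.subject_id}\n")
    cols = _expected_columns()
    buf.write(",".join(cols) + "\n")
    for i in range(rec.n_frames):
        cells = [str(i), _TIME_FMT % rec.times[i]]
        for k in range(len(KEYPOINT_NAMES)):
            if np.isfinite(rec.scores[i, k]):
                cells += [_COORD_FMT % v for v in rec.positions[i, k]]
                cells.append(_SCORE_FMT % rec.scores[i, k])
            else:
                cells += ["", "", "", ""]
        buf.write(",".join(cells) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_recording(path: str | Path) -> Recording:
    """Read a v1-dialect keypoint CSV.

    Raises
    ------
    FormatError
        If the header deviates from the dialect (the message names the first
        offending column).
    RecordingValidationError
        If timestamps are not strictly increasing or scores leave [0, 1].
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, dtype=float)

    expected = _expected_columns()
    got = list(df.columns)
    missing = [c for c in expected if c not in got]
    if missing:
        raise FormatError(f"missing required column {missing[0]!r}")
    extra = [c for c in got if c not in expected]
    if extra:
        raise FormatError(f"unexpected column {extra[0]!r}")

    n = len(df)
    times = df["time"].to_numpy()
    positions = np.empty((n, len(KEYPOINT_NAMES), 3))
    scores = np.empty((n, len(KEYPOINT_NAMES)))
    for k, name in enumerate(KEYPOINT_NAMES):
        positions[:, k, 0] = df[f"{name}_x"]
        positions[:, k, 1] = df[f"{name}_y"]
        positions[:, k, 2] = df[f"{name}_z"]
        scores[:, k] = df[f"{name}_score"]

    return Recording(
        times=times,
        positions=positions,
        scores=scores,
        fps=float(meta.get("fps", 30.0)),
        direction=meta.get("direction", "unknown"),
        subject_id=meta.get("subject_id", ""),
    )


def filter_by_score(rec: Recording, threshold: float = 0.7) -> Recording:
    """Drop samples whose confidence score is below ``threshold``.

    Frames are never dropped — only individual samples; downstream steps skip
    frames that no longer carry the keypoints they need.  Per-keypoint
    retained counts are reported at DEBUG level.  Idempotent and monotone in
    the threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    positions = rec.positions.copy()
    scores = rec.scores.copy()
    with np.errstate(invalid="ignore"):
        drop = scores < threshold
    positions[drop] = np.nan
    scores[drop] = np.nan
    if logger.isEnabledFor(logging.DEBUG):
        kept = np.isfinite(scores).sum(axis=0)
        for k, name in enumerate(KEYPOINT_NAMES):
            logger.debug("filter_by_score: %s retained %d/%d", name, kept[k], rec.n_frames)
    return replace(rec, times=rec.times.copy(), positions=positions, scores=scores,
                   labels=dict(rec.labels))


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort manifest CSV (`subject_id,path,label_*` with 0/1 labels)."""
    cols = ["subject_id", "path", *MANIFEST_LABEL_COLUMNS]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing column {missing[0]!r}")
    df[cols].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; label columns are coerced to bool."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("subject_id", "path"):
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
    for col in MANIFEST_LABEL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
        df[col] = df[col].astype(int).astype(bool)
    if len(df) == 0:
        raise RecordingValidationError("manifest is empty")
    # resolve paths relative to the manifest location
    base = path.parent
    df["path"] = [str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]]
    return df
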