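"""Shared fixtures: simulated recordings and projected tracks.

Everything is generated programmatically with fixed seeds; heavy objects are
session-scoped so the pipeline runs once per preset.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitplane import (
    Recording,
    preset,
    project_recording,
    simulate_recording,
)
from gaitplane.keypoints import KEYPOINT_NAMES

SEED = 7


@pytest.fixture(scope="session")
def normal_recording() -> Recording:
    return simulate_recording(preset("normal", seed=SEED), subject_id="fix-normal")


@pytest.fixture(scope="session")
def clean_recording() -> Recording:
    """Noise-free, dropout-free normal walk for exact kinematic assertions."""
    params = preset("normal", seed=SEED, noise_sd=0.0, dropout_rate=0.0)
    return simulate_recording(params, subject_id="fix-clean")


@pytest.fixture(scope="session")
def preset_tracks():
    """Projected tracks for all four gait presets (same seed)."""
    out = {}
    for name in ("normal", "shuffling", "short_stepped", "wide_based"):
        rec = simulate_recording(preset(name, seed=SEED))
        out[name] = project_recording(rec)
    return out


@pytest.fixture(scope="session")
def normal_tracks(preset_tracks):
    return preset_tracks["normal"]


def rigid_transform(rec: Recording, rotation: np.ndarray, translation: np.ndarray,
                    ) -> Recording:
    """Apply one rigid motion to every keypoint of every frame."""
    pos = np.einsum("ij,nkj->nki", rotation, rec.positions) + translation
    return Recording(times=rec.times.copy(), positions=pos, scores=rec.scores.copy(),
                     fps=rec.fps, direction=rec.direction, subject_id=rec.subject_id)


def mirror_recording(rec: Recording) -> Recording:
    """Mirror left/right: negate x and swap the _l/_r keypoint labels."""
    pos = rec.positions.copy()
    pos[:, :, 0] *= -1.0
    perm = []
    for name in KEYPOINT_NAMES:
        if name.endswith("_l"):
            perm.append(KEYPOINT_NAMES.index(name[:-2] + "_r"))
        elif name.endswith("_r"):
            perm.append(KEYPOINT_NAMES.index(name[:-2] + "_l"))
        else:
            perm.append(KEYPOINT_NAMES.index(name))
    return Recording(times=rec.times.copy(), positions=pos[:, perm],
                     scores=rec.scores[:, perm].copy(), fps=rec.fps,
                     direction=rec.direction, subject_id=rec.subject_id)


def symmetric_cloud(cx: float, cy: float, spread: float = 0.01, n: int = 8,
                    ) -> np.ndarray:
    """A circular point cloud whose mean is exactly (cx, cy)."""
    ang = np.arange(n) * 2.0 * np.pi / n
    return np.column_stack([cx + spread * np.cos(ang), cy + spread * np.sin(ang)])
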