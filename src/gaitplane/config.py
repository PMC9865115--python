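"""Run configuration shared by the CLI and batch helpers."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .indices import CutoffConfig


@dataclass
class RunConfig:
    """Defaults mirror the published analysis settings.

    score_threshold 0.7 (confidence filter), ellipse_level 0.75 (tolerance
    ellipses), cutoffs as printed; everything is overridable.
    """

    score_threshold: float = 0.7
    ellipse_level: float = 0.75
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    area_convention: str = "semi"        # 'semi' | 'full_axis'
    amplitude_mode: str = "ellipse"      # 'ellipse' | 'raw'
    side_aggregation: str = "mean"       # documented; per-side values always kept
    seed: int = 0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must lie in [0, 1]")
        if not 0.0 < self.ellipse_level < 1.0:
            raise ValueError("ellipse_level must lie in (0, 1)")
        if self.area_convention not in ("semi", "full_axis"):
            raise ValueError(f"unknown area convention {self.area_convention!r}")
        if self.amplitude_mode not in ("ellipse", "raw"):
            raise ValueError(f"unknown amplitude mode {self.amplitude_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        """Stable short hash of the configuration, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config_file(path: str | Path) -> dict:
    """Flat ``key = value`` text config; '#' starts a comment."""
    values: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    return values
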