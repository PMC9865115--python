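"""Cohort-level detectability of gait features from single indices.

Given one scalar index per recording and boolean gait-feature labels, this
module evaluates a screening rule the way diagnostic-test studies report it:
confusion counts at a fixed cutoff (strict inequality in a stated
direction), sensitivity and specificity, the 2×2 odds ratio with a Woolf
logit 95% CI (Haldane–Anscombe +0.5 correction when a cell is empty), and
the ROC AUC via the Mann–Whitney statistic with a DeLong 95% CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .body_frame import project_recording
from .indices import CutoffConfig, compute_indices
from .io import read_manifest, read_recording

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class CohortError(ValueError):
    """The cohort cannot be evaluated (e.g. a class is absent)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


@dataclass(frozen=True)
class OddsRatioResult:
    value: float
    lo: float
    hi: float
    corrected: bool = False  # Haldane–Anscombe +0.5 applied


@dataclass(frozen=True)
class AUCResult:
    value: float
    lo: float
    hi: float
    degenerate: bool = False  # all values tied


#: Table rows evaluated by cohort_report: (feature, index, cutoff attr, direction).
FEATURE_INDEX_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("shuffling", "hip_angle_range", "hip_angle", "below"),
    ("shuffling", "knee_angle_range", "knee_angle", "below"),
    ("shuffling", "heel_vertical_amplitude", "heel_amplitude", "below"),
    ("short_stepped", "knee_angle_range", "knee_angle", "below"),
    ("wide_based", "heel_outward_shift", "heel_shift", "above"),
    ("wide_based", "toe_outward_shift", "toe_shift", "above"),
    ("wide_based", "leg_outward_shift", "leg_shift", "above"),
)

#: The single index most specific to each simulated gait feature.
MATCHING_INDEX: dict[str, str] = {
    "shuffling": "heel_vertical_amplitude",
    "short_stepped": "knee_angle_range",
    "wide_based": "leg_outward_shift",
}


def _clean(values, labels) -> tuple[np.ndarray, np.ndarray, int]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1D sequences")
    keep = np.isfinite(v)
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("excluding %d undefined value(s) from screening", n_excluded)
    v, y = v[keep], y[keep]
    if not (np.any(y) and np.any(~y)):
        raise CohortError("both classes must be present")
    return v, y, n_excluded


def confusion_at_cutoff(values, labels, cutoff: float,
                        direction: str = "below") -> ConfusionCounts:
    """2×2 counts with strict-inequality thresholding.

    direction='below': a value strictly below the cutoff is a positive call;
    direction='above': strictly above.  Values equal to the cutoff are
    negative calls.  NaN values are excluded (count reported).
    """
    if direction not in ("below", "above"):
        raise ValueError(f"unknown direction {direction!r}")
    v, y, n_excluded = _clean(values, labels)
    call = v < cutoff if direction == "below" else v > cutoff
    return ConfusionCounts(
        tp=int(np.sum(call & y)), fp=int(np.sum(call & ~y)),
        tn=int(np.sum(~call & ~y)), fn=int(np.sum(~call & y)),
        n_excluded=n_excluded,
    )


def odds_ratio(counts: ConfusionCounts) -> OddsRatioResult:
    """OR = (TP·TN)/(FN·FP) with a Woolf logit 95% CI.

    Any empty cell triggers the Haldane–Anscombe +0.5 correction on all four
    cells (flagged in the result).
    """
    cells = np.array([counts.tp, counts.fp, counts.tn, counts.fn], dtype=float)
    if np.any(cells < 0):
        raise ValueError("counts must be nonnegative")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    tp, fp, tn, fn = cells
    or_ = (tp * tn) / (fn * fp)
    se = float(np.sqrt((1 / cells).sum()))
    log_or = float(np.log(or_))
    return OddsRatioResult(value=float(or_), lo=float(np.exp(log_or - _Z95 * se)),
                           hi=float(np.exp(log_or + _Z95 * se)), corrected=corrected)


def or_from_sens_spec(sens: float, spec: float) -> float:
    """Odds ratio implied by a sensitivity/specificity operating point.

    Algebra over the same 2×2 table: OR = [sens/(1−sens)] · [spec/(1−spec)].
    Boundary values give an infinite or zero OR.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if sens in (0.0, 1.0) or spec in (0.0, 1.0):
        logger.warning("boundary sensitivity/specificity: OR is 0 or infinite")
        if sens == 1.0 or spec == 1.0:
            return float("inf") if (sens > 0.0 and spec > 0.0) else float("nan")
        return 0.0
    return float((sens / (1.0 - sens)) * (spec / (1.0 - spec)))


def _placement_values(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: per-case and per-control placements."""
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / neg.size
    pos_sorted = np.sort(pos)
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    v01 = 1.0 - (lo + 0.5 * (hi - lo)) / pos.size
    return v10, v01


def roc_auc(values, labels, direction: str = "above") -> AUCResult:
    """ROC AUC with tie correction and a DeLong 95% CI.

    direction='above' treats larger values as more case-like; 'below' flips
    the sign.  If every value is tied the AUC is 0.5 with a degenerate CI.
    """
    if direction not in ("below", "above"):
        raise ValueError(f"unknown direction {direction!r}")
    v, y, _ = _clean(values, labels)
    scores = -v if direction == "below" else v
    if np.unique(scores).size < 2:
        return AUCResult(0.5, 0.0, 1.0, degenerate=True)
    pos, neg = scores[y], scores[~y]
    ranks = stats.rankdata(scores)
    n1, n0 = pos.size, neg.size
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    v10, v01 = _placement_values(pos, neg)
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
    se = float(np.sqrt(var))
    return AUCResult(value=float(auc), lo=float(max(0.0, auc - _Z95 * se)),
                     hi=float(min(1.0, auc + _Z95 * se)))


def screen_cohort(index_table: pd.DataFrame,
                  cutoffs: CutoffConfig | None = None) -> pd.DataFrame:
    """Evaluate every (feature, index) screening rule on a per-recording table.

    ``index_table`` needs one row per recording with the index columns named
    as in ``GaitIndexSet`` and boolean ``label_<feature>`` columns.  Returns
    one row per rule with AUC/CI, sensitivity, specificity, OR/CI and counts.
    """
    cfg = cutoffs or CutoffConfig()
    rows = []
    for feature, index_name, cut_attr, direction in FEATURE_INDEX_ROWS:
        label_col = f"label_{feature}"
        if label_col not in index_table.columns or index_name not in index_table.columns:
            continue
        values = index_table[index_name].to_numpy(dtype=float)
        labels = index_table[label_col].to_numpy(dtype=bool)
        if labels.all() or not labels.any():
            logger.warning("feature %s has a single-class label column; skipped",
                           feature)
            continue
        cutoff = float(getattr(cfg, cut_attr))
        counts = confusion_at_cutoff(values, labels, cutoff, direction)
        auc = roc_auc(values, labels, direction)
        orr = odds_ratio(counts)
        rows.append({
            "feature": feature, "index": index_name, "cutoff": cutoff,
            "direction": direction,
            "auc": auc.value, "auc_lo": auc.lo, "auc_hi": auc.hi,
            "sens": counts.sensitivity, "spec": counts.specificity,
            "or": orr.value, "or_lo": orr.lo, "or_hi": orr.hi,
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        })
    return pd.DataFrame(rows)


def index_table_from_recordings(recordings, labels: pd.DataFrame | None = None,
                                level: float = 0.75, score_threshold: float = 0.7,
                                amplitude_mode: str = "ellipse") -> pd.DataFrame:
    """Run the full pipeline on in-memory recordings -> per-recording indices.

    ``labels`` (optional) supplies subject_id + label_* columns; otherwise
    labels attached to each recording are used.
    """
    rows = []
    for i, rec in enumerate(recordings):
        tracks = project_recording(rec, score_threshold=score_threshold)
        report = compute_indices(tracks, level=level, amplitude_mode=amplitude_mode)
        row = {"subject_id": rec.subject_id or f"rec{i}"}
        row.update(report.indices.to_dict())
        for feat, val in rec.labels.items():
            row[f"label_{feat}"] = bool(val)
        rows.append(row)
    table = pd.DataFrame(rows)
    if labels is not None:
        table = table.drop(columns=[c for c in table.columns if c.startswith("label_")])
        table = table.merge(labels, on="subject_id", how="left")
    return table


def cohort_report(manifest_path, level: float = 0.75, score_threshold: float = 0.7,
                  cutoffs: CutoffConfig | None = None,
                  amplitude_mode: str = "ellipse",
                  ) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Analyze every recording in a manifest and screen all features.

    Returns (screening table, per-recording index table, skip report).
    Unreadable or unanalyzable recordings are skipped and listed, never fatal
    unless a class disappears entirely.
    """
    manifest = read_manifest(manifest_path)
    rows, skipped = [], []
    for rec_row in manifest.itertuples(index=False):
        try:
            rec = read_recording(rec_row.path)
            tracks = project_recording(rec, score_threshold=score_threshold)
            report = compute_indices(tracks, level=level, amplitude_mode=amplitude_mode)
        except (OSError, ValueError) as exc:
            skipped.append({"subject_id": rec_row.subject_id, "path": rec_row.path,
                            "reason": str(exc)})
            continue
        row = {"subject_id": rec_row.subject_id}
        row.update(report.indices.to_dict())
        for col in manifest.columns:
            if col.startswith("label_"):
                row[col] = bool(getattr(rec_row, col))
        rows.append(row)
    if not rows:
        raise CohortError("no analyzable recordings in manifest")
    index_table = pd.DataFrame(rows)
    table = screen_cohort(index_table, cutoffs)
    if table.empty:
        raise CohortError(
            "no gait feature has both classes present (label columns are "
            "all-zero or all-one)")
    return table, index_table, skipped
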