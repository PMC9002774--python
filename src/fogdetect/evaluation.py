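"""Window-level metrics, majority-vote smoothing, and episode detection.

A true positive is a window labelled FOG and classified FOG; the five
classification metrics follow the standard confusion-count definitions
(sensitivity, specificity, precision, accuracy, F-score). Metrics with a zero
denominator are reported as NaN ("not available") rather than coerced to 0,
so averages are never silently inflated.

Majority voting smooths the per-window prediction stream with a centered
5-window majority (about 4 s at the 0.3-s window step), removing isolated
classification errors while keeping time resolution compatible with short
FOG episodes. At stream edges the vote shrinks to the available neighbours;
an even-count tie keeps the original prediction.

Episode-level accounting: an annotated episode (after the < 3 s exclusion)
counts as detected when at least one smoothed FOG-predicted window overlaps
it; the required overlap fraction is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AnnotationSet, Window

MV_SPAN = 5


@dataclass
class EvaluationReport:
    """Confusion counts, the five metrics, and episode-level tallies."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_score: float
    episode_total: int = 0
    episode_detected: int = 0
    mode: str = "SIA"
    mv_applied: bool = False
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "accuracy": self.accuracy,
            "f_score": self.f_score, "episode_total": self.episode_total,
            "episode_detected": self.episode_detected, "mode": self.mode,
            "mv_applied": self.mv_applied,
        }
        out.update(self.extra)
        return out


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_and_metrics(
    predictions: np.ndarray,
    labels: np.ndarray,
    mode: str = "SIA",
    mv_applied: bool = False,
) -> EvaluationReport:
    """Confusion counts and metrics for aligned 0/1 prediction/label vectors."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels are misaligned")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    f = (
        _safe_div(2.0 * prec * sens, prec + sens)
        if np.isfinite(prec) and np.isfinite(sens)
        else float("nan")
    )
    return EvaluationReport(tp, fp, fn, tn, sens, spec, prec, acc, f,
                            mode=mode, mv_applied=mv_applied)


def majority_vote(predictions: np.ndarray, span: int = MV_SPAN) -> np.ndarray:
    """Centered sliding-majority smoothing of one ordered prediction stream.

    Each position takes the majority label of the up-to-``span`` predictions
    centered on it; shrunken neighbourhoods are used at the edges, and an
    exact tie keeps the original prediction.
    """
    predictions = np.asarray(predictions, dtype=int)
    n = predictions.size
    half = span // 2
    out = predictions.copy()
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        votes = predictions[lo:hi]
        ones = int(votes.sum())
        zeros = votes.size - ones
        if ones > zeros:
            out[i] = 1
        elif zeros > ones:
            out[i] = 0
        # tie: keep original
    return out


def majority_vote_by_task(
    predictions: np.ndarray, windows: list[Window], span: int = MV_SPAN
) -> np.ndarray:
    """Apply majority voting independently within each (subject, task) stream,
    ordered by window start time."""
    predictions = np.asarray(predictions, dtype=int)
    out = predictions.copy()
    keys = [(w.subject_id, w.task_id) for w in windows]
    for key in sorted(set(keys)):
        idx = np.array([i for i, k in enumerate(keys) if k == key])
        order = idx[np.argsort([windows[i].start_s for i in idx])]
        out[order] = majority_vote(predictions[order], span)
    return out


def episode_detection(
    predictions: np.ndarray,
    windows: list[Window],
    annotations: AnnotationSet,
    min_overlap_fraction: float = 0.0,
) -> tuple[int, int]:
    """Count (episode_total, episode_detected).

    An episode is detected when a FOG-predicted window overlaps it by strictly
    more than ``min_overlap_fraction`` of the episode duration (default: any
    positive overlap). ``annotations`` must already have short episodes
    excluded.
    """
    predictions = np.asarray(predictions, dtype=int)
    detected = 0
    for ep in annotations.episodes:
        need = min_overlap_fraction * ep.duration_s
        hit = False
        for pred, w in zip(predictions, windows):
            if pred != 1 or (w.subject_id, w.task_id) != (ep.subject_id, ep.task_id):
                continue
            overlap = min(w.end_s, ep.end_s) - max(w.start_s, ep.start_s)
            if overlap > need:
                hit = True
                break
        detected += int(hit)
    return len(annotations.episodes), detected


__all__ = [
    "MV_SPAN",
    "EvaluationReport",
    "confusion_and_metrics",
    "majority_vote",
    "majority_vote_by_task",
    "episode_detection",
]
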