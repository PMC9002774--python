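"""End-to-end orchestration: simulate -> preprocess -> window -> features ->
select -> model -> evaluate, with reproducible artifacts.

:func:`run_sia_cohort` and :func:`run_sda_subject` are the in-memory entry
points; :func:`run` drives a full configured run and writes every intermediate
artifact (window table, feature matrix + dictionary, per-fold selections,
fold results, evaluation report, resolved config) into a run directory.
Identical config + seed produce identical artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, modeling
from .evaluation import (
    EvaluationReport,
    confusion_and_metrics,
    episode_detection,
    majority_vote_by_task,
)
from .features import FeatureMatrix, concat_feature_matrices, extract_features
from .preprocess import DEFAULT_MONTAGE, preprocess_recording
from .synth import CohortParams, simulate_cohort
from .types import AnnotationSet, Recording, WindowSet
from .windowing import exclude_short_episodes, segment

#: Modalities each sensor group needs, so preprocessing can skip the rest.
SENSOR_MODALITIES = {
    "tibia": ("tibia_acc", "tibia_gyro"),
    "wrist": ("wrist_acc", "wrist_gyro"),
    "eeg": ("eeg",),
    "sc": ("sc",),
}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study's stated values
    (3-s windows at 90 % overlap, |r| thresholds 0.35 / 0.4, cross-r 0.86,
    p < 0.05, 5-epoch majority vote, 500 Hz common rate)."""

    mode: str = "sia"  # "sia" | "sda"
    sensors: tuple[str, ...] = ("tibia",)
    grid: str = "small"  # "small" | "full"
    seed: int = 0
    # cohort
    n_subjects: int = 8
    tasks_per_subject: int = 2
    task_duration_s: float = 120.0
    fog_rate: float = 2.0
    fog_amplitude_ratio: float = 0.5
    # analysis
    window_len_s: float = 3.0
    overlap: float = 0.9
    min_episode_s: float = 3.0
    mv_span: int = 5
    r_thresh: float | None = None
    write_signals: bool = False

    def cohort_params(self) -> CohortParams:
        return CohortParams(
            n_subjects=self.n_subjects,
            tasks_per_subject=self.tasks_per_subject,
            task_duration_s=self.task_duration_s,
            fog_rate=self.fog_rate,
            fog_amplitude_ratio=self.fog_amplitude_ratio,
            seed=self.seed,
        )

    def grid_cells(self) -> list[modeling.ModelSpec]:
        return modeling.full_grid() if self.grid == "full" else modeling.small_grid()


def preprocess_cohort(
    recordings: list[Recording],
    sensors: tuple[str, ...],
    montage=DEFAULT_MONTAGE,
) -> list[Recording]:
    """Preprocess only the modalities the requested sensor groups need."""
    needed = {m for s in sensors for m in SENSOR_MODALITIES[s]}
    out = []
    for rec in recordings:
        sub = Recording(
            rec.subject_id, rec.task_id,
            {k: v for k, v in rec.modalities.items() if k in needed},
        )
        out.append(preprocess_recording(sub, montage))
    return out


def build_feature_matrix(
    processed: list[Recording],
    annotations: AnnotationSet,
    sensors: tuple[str, ...],
    window_len_s: float = 3.0,
    overlap: float = 0.9,
) -> FeatureMatrix:
    matrices = []
    for rec in processed:
        ws = segment(rec, annotations, window_len_s, overlap)
        if len(ws) == 0:
            continue
        matrices.append(extract_features(rec, ws, sensors))
    return concat_feature_matrices(matrices)


@dataclass
class PipelineResult:
    """Everything a run computes, for reporting and inspection."""

    features: FeatureMatrix
    annotations: AnnotationSet  # after short-episode exclusion
    n_excluded_episodes: int
    cv: modeling.CrossValidationResult
    predictions_mv: np.ndarray
    report_raw: EvaluationReport
    report_mv: EvaluationReport
    extra: dict = field(default_factory=dict)


def _evaluate(
    cv: modeling.CrossValidationResult,
    matrix: FeatureMatrix,
    annotations: AnnotationSet,
    mode: str,
    mv_span: int,
) -> tuple[np.ndarray, EvaluationReport, EvaluationReport]:
    windows = matrix.windows.windows
    mask = cv.evaluated
    labels = matrix.labels
    raw = confusion_and_metrics(cv.predictions[mask], labels[mask], mode=mode)
    pred_mv_full = majority_vote_by_task(
        np.where(mask, cv.predictions, 0), windows, mv_span
    )
    mv = confusion_and_metrics(pred_mv_full[mask], labels[mask], mode=mode,
                               mv_applied=True)
    eval_windows = [w for w, m in zip(windows, mask) if m]
    total, detected = episode_detection(
        pred_mv_full[mask], eval_windows, annotations
    )
    mv.episode_total, mv.episode_detected = total, detected
    return pred_mv_full, raw, mv


def run_sia_cohort(
    params: CohortParams,
    sensors: tuple[str, ...] = ("tibia",),
    grid: list[modeling.ModelSpec] | None = None,
    r_thresh: float | None = None,
    min_episode_s: float = 3.0,
    mv_span: int = 5,
    seed: int | None = None,
) -> PipelineResult:
    """Simulate a cohort and evaluate the subject-independent algorithm."""
    recordings, annotations = simulate_cohort(params)
    annotations, n_excluded = exclude_short_episodes(annotations, min_episode_s)
    processed = preprocess_cohort(recordings, sensors)
    matrix = build_feature_matrix(processed, annotations, sensors)
    cv = modeling.sia_nested_loso(
        matrix, grid=grid, r_thresh=r_thresh,
        seed=params.seed if seed is None else seed,
    )
    pred_mv, raw, mv = _evaluate(cv, matrix, annotations, "SIA", mv_span)
    return PipelineResult(matrix, annotations, n_excluded, cv, pred_mv, raw, mv)


def run_sda_subject(
    matrix: FeatureMatrix,
    annotations: AnnotationSet,
    grid: list[modeling.ModelSpec] | None = None,
    r_thresh: float | None = None,
    mv_span: int = 5,
    seed: int = 0,
) -> PipelineResult:
    """Evaluate the subject-dependent algorithm on one subject's windows."""
    cv = modeling.sda_fit_evaluate(matrix, grid=grid, r_thresh=r_thresh, seed=seed)
    pred_mv, raw, mv = _evaluate(cv, matrix, annotations, "SDA", mv_span)
    return PipelineResult(matrix, annotations, 0, cv, pred_mv, raw, mv)


def _fold_table(cv: modeling.CrossValidationResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "test_id": f.test_id,
                "model_id": f.model_id,
                "n_test_windows": int(f.test_indices.size),
                "n_selected_features": len(f.selected_features),
                "selected_features": ";".join(f.selected_features),
            }
            for f in cv.folds
        ]
    )


def run(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    """Execute a configured run and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.cohort_params()
    grid = config.grid_cells()

    if config.mode == "sia":
        result = run_sia_cohort(
            params, config.sensors, grid, config.r_thresh,
            config.min_episode_s, config.mv_span, config.seed,
        )
    elif config.mode == "sda":
        recordings, annotations = simulate_cohort(params)
        annotations, n_exc = exclude_short_episodes(annotations, config.min_episode_s)
        processed = preprocess_cohort(recordings, config.sensors)
        # evaluate each eligible subject, pool window-level results
        results = []
        for sid in sorted({r.subject_id for r in processed}):
            recs = [r for r in processed if r.subject_id == sid]
            matrix = build_feature_matrix(
                recs, annotations, config.sensors,
                config.window_len_s, config.overlap,
            )
            try:
                results.append(
                    run_sda_subject(
                        matrix, annotations, grid, config.r_thresh,
                        config.mv_span, config.seed,
                    )
                )
            except ValueError:
                continue
        if not results:
            raise RuntimeError("no subject was eligible for the SDA analysis")
        matrix = concat_feature_matrices([r.features for r in results])
        pred = np.concatenate([r.cv.predictions for r in results])
        pred_mv = np.concatenate([r.predictions_mv for r in results])
        mask = pred >= 0
        folds = [f for r in results for f in r.cv.folds]
        cv = modeling.CrossValidationResult(folds, pred, mask, "SDA")
        raw = confusion_and_metrics(pred[mask], matrix.labels[mask], mode="SDA")
        mv = confusion_and_metrics(
            pred_mv[mask], matrix.labels[mask], mode="SDA", mv_applied=True
        )
        eval_windows = [w for w, m in zip(matrix.windows.windows, mask) if m]
        mv.episode_total, mv.episode_detected = episode_detection(
            pred_mv[mask], eval_windows, annotations
        )
        result = PipelineResult(matrix, annotations, n_exc, cv, pred_mv, raw, mv)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    if config.write_signals:
        recordings, raw_ann = simulate_cohort(params)
        io.write_cohort(recordings, raw_ann, out / "raw")

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    io.write_windows(result.features.windows, out / "windows.csv")
    result.features.data.to_csv(out / "features.csv", index=False,
                                float_format="%.9g")
    result.features.feature_dictionary().to_csv(
        out / "feature_dictionary.csv", index=False
    )
    io.write_annotations(result.annotations, out / "annotations_filtered.csv")
    _fold_table(result.cv).to_csv(out / "folds.csv", index=False)
    pd.DataFrame(
        {
            "prediction": result.cv.predictions,
            "prediction_mv": result.predictions_mv,
            "label": result.features.labels,
        }
    ).to_csv(out / "predictions.csv", index=False)
    io.write_json(
        {
            "raw": result.report_raw.to_dict(),
            "majority_vote": result.report_mv.to_dict(),
            "n_excluded_episodes": result.n_excluded_episodes,
        },
        out / "evaluation.json",
    )
    return result


__all__ = [
    "RunConfig",
    "PipelineResult",
    "SENSOR_MODALITIES",
    "preprocess_cohort",
    "build_feature_matrix",
    "run_sia_cohort",
    "run_sda_subject",
    "run",
]
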