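"""Subject-dependent FOG detection: 10-fold CV + leave-one-task-out.

Selection uses the stricter per-subject threshold (|r| >= 0.4). Each task is
held out in turn; hyperparameters are chosen by stratified cross-validation
on the remaining tasks' windows.
"""

import warnings

from fogdetect import exclude_short_episodes, run_sda_subject
from fogdetect.modeling import small_grid
from fogdetect.pipeline import build_feature_matrix, preprocess_cohort
from fogdetect.synth import CohortParams, simulate_subject

params = CohortParams(n_subjects=1, tasks_per_subject=3, task_duration_s=90.0,
                      fog_rate=2.5, seed=23)
recordings, annotations = simulate_subject(params, 0)
annotations, _ = exclude_short_episodes(annotations)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    processed = preprocess_cohort(list(recordings.values()), ("tibia",))
    matrix = build_feature_matrix(processed, annotations, ("tibia",))
    result = run_sda_subject(matrix, annotations, grid=small_grid())

for fold in result.cv.folds:
    print(f"  held-out {fold.test_id}: chose {fold.model_id} "
          f"({len(fold.selected_features)} features)")
mv = result.report_mv
print(f"after majority voting: accuracy {mv.accuracy:.1%}, "
      f"F-score {mv.f_score:.1%}")
print(f"episodes detected: {mv.episode_detected}/{mv.episode_total}")
# A per-patient model can exploit idiosyncratic FOG signatures (e.g. wrist
# trembling vs arm-swing suppression) that do not generalize across subjects.
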