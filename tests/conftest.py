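"""Shared fixtures: small synthetic cohorts and constructed feature matrices."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import fogdetect as fd
from fogdetect.features import FeatureMatrix
from fogdetect.modeling import small_grid
from fogdetect.synth import CohortParams
from fogdetect.types import Window, WindowSet


@pytest.fixture(scope="session")
def small_processed():
    """One preprocessed 60-s recording with windows and the full feature
    battery (all four sensor groups)."""
    params = CohortParams(
        n_subjects=1, tasks_per_subject=1, task_duration_s=60.0, fog_rate=3.0,
        seed=17,
    )
    recs, anns = fd.simulate_subject(params, 0)
    rec = recs["T1"]
    anns, _ = fd.exclude_short_episodes(anns)
    proc = fd.preprocess_recording(rec)
    windows = fd.segment(proc, anns)
    matrix = fd.extract_features(proc, windows)
    return proc, anns, windows, matrix


@pytest.fixture(scope="session")
def e2e_sia():
    """The subject-independent end-to-end run on the default synthetic cohort
    (8 subjects, 2 tasks x 120 s, 2 episodes/min, amplitude ratio 0.5,
    seed 42), restricted to the tibial sensors."""
    params = CohortParams(seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fd.run_sia_cohort(params, sensors=("tibia",), grid=small_grid())


def make_labeled_matrix(
    n_subjects: int = 4,
    n_per_subject: int = 120,
    n_tasks: int = 2,
    seed: int = 0,
    oracle: bool = True,
    fog_fraction: float = 0.35,
) -> FeatureMatrix:
    """Construct a synthetic window/feature matrix directly (no signals):
    one informative 'oracle' feature plus noise columns."""
    rng = np.random.default_rng(seed)
    windows = []
    rows = []
    per_task = n_per_subject // n_tasks
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        for t in range(n_tasks):
            tid = f"T{t + 1}"
            labels = (rng.random(per_task) < fog_fraction).astype(int)
            for i, lab in enumerate(labels):
                start = i * 0.3
                windows.append(Window(sid, tid, start, start + 3.0, int(lab)))
                rows.append(lab)
    y = np.array(rows, dtype=float)
    n = y.size
    data = {
        "noise_a": rng.standard_normal(n),
        "noise_b": rng.standard_normal(n),
    }
    if oracle:
        data["oracle"] = y + 0.05 * rng.standard_normal(n)
    df = pd.DataFrame(data)
    registry = [
        {"name": c, "sensor": "synthetic", "channel": "", "domain": "time",
         "band": ""}
        for c in df.columns
    ]
    return FeatureMatrix(df, registry, WindowSet(windows))
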