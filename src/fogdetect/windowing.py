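"""Fixed-length overlapping windows and sample-majority labelling.

The analysis grid is 3-s windows with 90 % overlap (0.3 s step), anchored at
t = 0 of each task recording. A window is labelled FOG when strictly more than
half of its samples fall inside an annotated episode; the tie at exactly half
is broken toward non-FOG ("largest number of samples" implies strict
majority, and this is conservative toward the negative class).
"""

from __future__ import annotations

import warnings

from .types import AnnotationSet, Episode, Recording, Window, WindowSet

WINDOW_LEN_S = 3.0
OVERLAP = 0.9


def exclude_short_episodes(
    annotations: AnnotationSet, min_len_s: float = 3.0
) -> tuple[AnnotationSet, int]:
    """Drop episodes shorter than ``min_len_s`` (strictly less than).

    Episodes below the detector's post-smoothing time resolution cannot be
    resolved and are excluded from the analysis. Returns the filtered set and
    the number of removed episodes.
    """
    kept = [e for e in annotations.episodes if e.duration_s >= min_len_s]
    return AnnotationSet(kept), len(annotations.episodes) - len(kept)


def _overlap_s(start_s: float, end_s: float, episodes: list[Episode]) -> float:
    """Total time of [start_s, end_s) covered by episodes (half-open)."""
    total = 0.0
    for ep in episodes:
        total += max(0.0, min(end_s, ep.end_s) - max(start_s, ep.start_s))
    return total


def label_window(
    start_s: float,
    end_s: float,
    annotations: AnnotationSet,
    subject_id: str,
    task_id: str,
) -> int:
    """1 (FOG) iff strictly more than half the window lies inside episodes."""
    if not end_s > start_s:
        raise ValueError("window must have positive length")
    episodes = annotations.for_task(subject_id, task_id)
    inside = _overlap_s(start_s, end_s, episodes)
    return int(inside > 0.5 * (end_s - start_s))


def n_windows(duration_s: float, window_len_s: float = WINDOW_LEN_S,
              overlap: float = OVERLAP) -> int:
    """Number of grid windows: floor((T - L) / step) + 1, or 0 if T < L."""
    step = window_len_s * (1.0 - overlap)
    if duration_s < window_len_s:
        return 0
    # guard against float fuzz at exact multiples of the step
    return int((duration_s - window_len_s) / step + 1e-9) + 1


def segment(
    recording: Recording,
    annotations: AnnotationSet,
    window_len_s: float = WINDOW_LEN_S,
    overlap: float = OVERLAP,
) -> WindowSet:
    """Cut one recording into labelled windows on the fixed grid.

    Requires every modality at a common rate (500 Hz after preprocessing);
    windows start at 0, step, 2*step, ... while they fit entirely inside the
    recording.
    """
    duration = recording.duration_s
    step = window_len_s * (1.0 - overlap)
    count = n_windows(duration, window_len_s, overlap)
    if count == 0:
        warnings.warn(
            f"recording {recording.subject_id}/{recording.task_id} shorter "
            f"than one window ({duration:.2f}s < {window_len_s}s)",
            stacklevel=2,
        )
        return WindowSet([], window_len_s, overlap)
    windows = []
    for i in range(count):
        start = i * step
        end = start + window_len_s
        windows.append(
            Window(
                recording.subject_id,
                recording.task_id,
                start,
                end,
                label_window(
                    start, end, annotations, recording.subject_id,
                    recording.task_id,
                ),
            )
        )
    return WindowSet(windows, window_len_s, overlap)


def window_slice(window: Window, fs: float) -> slice:
    """Sample slice of a window at rate ``fs`` (half-open)."""
    start = int(round(window.start_s * fs))
    return slice(start, start + int(round((window.end_s - window.start_s) * fs)))


__all__ = [
    "WINDOW_LEN_S",
    "OVERLAP",
    "exclude_short_episodes",
    "label_window",
    "n_windows",
    "segment",
    "window_slice",
]
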