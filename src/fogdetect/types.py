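"""Core containers shared by every pipeline stage.

A :class:`Recording` holds the raw or processed multi-modal signals of one
subject performing one task; an :class:`AnnotationSet` holds the clinician-style
freezing-of-gait (FOG) episode intervals; a :class:`WindowSet` holds the fixed
3-s, 90 %-overlap analysis windows with their binary labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Modality names used throughout the package.
MODALITIES = ("tibia_acc", "tibia_gyro", "wrist_acc", "wrist_gyro", "eeg", "sc")

#: Modalities that are tri-axial inertial sensors.
INERTIAL_MODALITIES = ("tibia_acc", "tibia_gyro", "wrist_acc", "wrist_gyro")


@dataclass
class ModalityData:
    """Samples of one modality: ``samples`` is (n_channels, n_samples)."""

    channel_names: list[str]
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} rows"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None
        return self.samples[idx]


@dataclass
class Recording:
    """Multi-modal recording of one subject performing one task."""

    subject_id: str
    task_id: str
    modalities: dict[str, ModalityData] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mod in self.modalities.items():
            if name in INERTIAL_MODALITIES and mod.samples.shape[0] != 3:
                raise ValueError(f"{name} must have exactly 3 channels (x, y, z)")
            # raw sc is single-channel; after preprocessing it carries the
            # filtered conductance plus its phasic/tonic split (3 channels)
            if name == "sc" and mod.samples.shape[0] not in (1, 3):
                raise ValueError("sc must have 1 channel (raw) or 3 (processed)")

    @property
    def duration_s(self) -> float:
        return min(m.duration_s for m in self.modalities.values())


@dataclass(frozen=True)
class Episode:
    """One annotated FOG episode (times in seconds from task start)."""

    subject_id: str
    task_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("episode must have start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationSet:
    """FOG episodes for a cohort; per (subject, task) they are sorted and disjoint."""

    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.episodes = sorted(
            self.episodes, key=lambda e: (e.subject_id, e.task_id, e.start_s)
        )
        prev: Episode | None = None
        for ep in self.episodes:
            if (
                prev is not None
                and (ep.subject_id, ep.task_id) == (prev.subject_id, prev.task_id)
                and ep.start_s < prev.end_s
            ):
                raise ValueError(
                    f"overlapping episodes for {ep.subject_id}/{ep.task_id}"
                )
            prev = ep

    def for_task(self, subject_id: str, task_id: str) -> list[Episode]:
        return [
            e
            for e in self.episodes
            if e.subject_id == subject_id and e.task_id == task_id
        ]

    def __len__(self) -> int:
        return len(self.episodes)


@dataclass(frozen=True)
class Window:
    """One fixed-length analysis window; label is 1 for FOG, 0 for non-FOG."""

    subject_id: str
    task_id: str
    start_s: float
    end_s: float
    label: int


@dataclass
class WindowSet:
    """Overlapping fixed-length windows over one or more recordings."""

    windows: list[Window] = field(default_factory=list)
    window_len_s: float = 3.0
    overlap: float = 0.9

    @property
    def step_s(self) -> float:
        return self.window_len_s * (1.0 - self.overlap)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def __len__(self) -> int:
        return len(self.windows)

    def __add__(self, other: "WindowSet") -> "WindowSet":
        if (self.window_len_s, self.overlap) != (other.window_len_s, other.overlap):
            raise ValueError("cannot concatenate WindowSets with different grids")
        return WindowSet(
            self.windows + other.windows, self.window_len_s, self.overlap
        )


__all__ = [
    "MODALITIES",
    "INERTIAL_MODALITIES",
    "ModalityData",
    "Recording",
    "Episode",
    "AnnotationSet",
    "Window",
    "WindowSet",
    "replace",
]
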