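"""Synthetic multi-modal cohorts with ground-truth freezing-of-gait episodes.

The generator emulates the signal structure the downstream analysis relies on:

* **Inertial (tibia, wrist)** — walking segments are a gait fundamental
  (per-subject, ~1-2.5 Hz) plus two harmonics, so spectral power concentrates
  in the 0.5-3 Hz locomotion band; FOG segments are a trembling oscillation in
  the 3-8 Hz freeze band with reduced amplitude.
* **EEG** — 28 raw electrodes of pink noise, with band-limited oscillators at
  fronto-central sites whose band powers shift during FOG.
* **Skin conductance** — slow tonic drift plus fast phasic (exponential-decay)
  responses that begin within 2 s before each episode onset; stored as galvanic
  resistance, the reciprocal of conductance, as a resistance sensor would
  deliver it.

Episode onsets follow a Poisson process with a refractory gap; durations are
log-normal, so most episodes are short (many below 10 s) while a few are very
long, matching the clinical distribution the analysis must cope with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import AnnotationSet, Episode, ModalityData, Recording

#: Raw electrode set (international 10-20 extended); IO is the ocular channel.
EEG_ELECTRODES = [
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "P7", "P8", "Fz", "Cz", "Pz", "FC1", "FC2", "CP1",
    "CP2", "FC5", "FC6", "CP5", "CP6", "TP9", "TP10", "IO",
]

#: Electrodes carrying the band-limited oscillators (fronto-central /
#: centro-parietal sites, where FOG-related rhythms are expected).
OSCILLATOR_SITES = ("Fz", "Cz", "Pz", "FC1", "FC2", "C3", "C4", "CP1", "CP2")

#: Oscillator centre frequency (Hz) and walking amplitude per EEG band.
EEG_OSCILLATORS = {
    "delta": (2.5, 0.8),
    "theta": (6.0, 1.0),
    "alpha": (10.0, 0.8),
    "beta1": (16.0, 0.5),
    "beta2": (25.0, 0.4),
}

#: Native sampling rates (Hz) mimicking typical acquisition hardware:
#: high-rate EEG, low-rate inertial and conductance front-ends.
NATIVE_FS = {
    "tibia_acc": 100.0,
    "tibia_gyro": 100.0,
    "wrist_acc": 100.0,
    "wrist_gyro": 100.0,
    "eeg": 1000.0,
    "sc": 100.0,
}


def _default_band_shift() -> dict[str, float]:
    # Power multipliers inside FOG episodes: theta rises at fronto-central
    # sites, high-beta coupling increases, delta drops slightly.
    return {"delta": 0.7, "theta": 2.0, "alpha": 1.0, "beta1": 1.6, "beta2": 1.6}


def _default_noise_sd() -> dict[str, float]:
    return {"inertial": 0.1, "eeg": 1.0, "sc": 0.01}


@dataclass
class CohortParams:
    """Study-condition parameters of a synthetic cohort.

    Defaults reproduce the conditions the end-to-end analysis is exercised
    under: 8 subjects, two ~2-minute walking tasks each, two FOG episodes per
    minute on average, trembling amplitude half the walking amplitude, and
    log-normal episode durations with median 8 s (so roughly half the episodes
    are shorter than 10 s and about a fifth fall under the 3-s exclusion rule).
    """

    n_subjects: int = 8
    tasks_per_subject: int = 2
    task_duration_s: float = 120.0
    fog_rate: float = 2.0  # episodes per minute (Poisson arrival rate)
    episode_median_s: float = 8.0
    episode_sigma: float = 1.2  # log-normal shape
    gait_freq_range_hz: tuple[float, float] = (1.0, 2.5)
    freeze_freq_range_hz: tuple[float, float] = (4.0, 7.0)
    fog_amplitude_ratio: float = 0.5
    eeg_fog_band_shift: dict[str, float] = field(default_factory=_default_band_shift)
    sc_phasic_gain: float = 0.3  # microsiemens, peak of one phasic response
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    refractory_s: float = 2.0  # minimum gap between consecutive episodes
    episode_min_s: float = 1.0
    episode_max_s: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        checks = {
            "n_subjects": self.n_subjects,
            "tasks_per_subject": self.tasks_per_subject,
            "task_duration_s": self.task_duration_s,
            "episode_median_s": self.episode_median_s,
            "episode_sigma": self.episode_sigma,
        }
        for name, value in checks.items():
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite, got {value!r}")
        if not np.isfinite(self.fog_rate) or self.fog_rate < 0:
            raise ValueError("fog_rate must be a finite non-negative rate")
        if not 0 < self.fog_amplitude_ratio < 1:
            raise ValueError("fog_amplitude_ratio must lie in (0, 1)")


def sample_episode_intervals(
    rng: np.random.Generator, params: CohortParams
) -> list[tuple[float, float]]:
    """Draw FOG episode (start, end) times for one task.

    Arrivals are a homogeneous Poisson process at ``fog_rate`` per minute;
    durations are log-normal (median ``episode_median_s``, shape
    ``episode_sigma``) clipped to [episode_min_s, episode_max_s]. Arrivals that
    cannot fit — overlapping the previous episode, violating the refractory
    gap, or overrunning the task — are discarded (thinning).
    """
    rate_per_s = params.fog_rate / 60.0
    intervals: list[tuple[float, float]] = []
    if rate_per_s == 0:
        return intervals
    t = 0.0
    last_end = -math.inf
    while True:
        t += rng.exponential(1.0 / rate_per_s)
        if t >= params.task_duration_s:
            break
        dur = float(
            np.clip(
                params.episode_median_s
                * np.exp(params.episode_sigma * rng.standard_normal()),
                params.episode_min_s,
                params.episode_max_s,
            )
        )
        if t < last_end + params.refractory_s:
            continue
        if t + dur > params.task_duration_s:
            continue
        intervals.append((t, t + dur))
        last_end = t + dur
    return intervals


def _regime_mask(n: int, fs: float, intervals: list[tuple[float, float]]) -> np.ndarray:
    """Boolean FOG mask over sample times (half-open [start, end) intervals)."""
    t = np.arange(n) / fs
    mask = np.zeros(n, dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nonzero = f > 0
    scale[nonzero] = 1.0 / np.sqrt(f[nonzero] / f[nonzero][0])
    pink = np.fft.irfft(spec * scale, n)
    return sd * pink / pink.std()


def _gait_waveform(
    rng: np.random.Generator, t: np.ndarray, f0: float, amps: tuple[float, ...]
) -> np.ndarray:
    out = np.zeros_like(t)
    for h, a in enumerate(amps, start=1):
        out += a * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
    return out


def _inertial_modality(
    rng: np.random.Generator,
    t: np.ndarray,
    fog: np.ndarray,
    gait_hz: float,
    freeze_hz: float,
    walk_amps: tuple[float, ...],
    fog_amp: float,
    noise_sd: float,
    fog_style: str = "tremble",
) -> np.ndarray:
    """Three channels: walking waveform outside episodes, FOG regime inside."""
    walking = ~fog
    channels = []
    for _ in range(3):
        walk = _gait_waveform(rng, t, gait_hz, walk_amps)
        if fog_style == "tremble":
            freeze = fog_amp * np.sin(
                2 * np.pi * freeze_hz * t + rng.uniform(0, 2 * np.pi)
            )
        else:  # attenuated arm swing: same pattern, much smaller
            freeze = 0.15 * walk
        x = walk * walking + freeze * fog + rng.normal(0, noise_sd, t.size)
        channels.append(x)
    return np.vstack(channels)


def _eeg_modality(
    rng: np.random.Generator,
    t: np.ndarray,
    fog: np.ndarray,
    band_shift: dict[str, float],
    noise_sd: float,
) -> np.ndarray:
    n = t.size
    rows = []
    for name in EEG_ELECTRODES:
        x = _pink_noise(rng, n, noise_sd)
        if name in OSCILLATOR_SITES:
            for band, (freq, amp) in EEG_OSCILLATORS.items():
                gain = np.where(fog, math.sqrt(band_shift.get(band, 1.0)), 1.0)
                x = x + gain * amp * np.sin(
                    2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
                )
        rows.append(x)
    return np.vstack(rows)


def _sc_modality(
    rng: np.random.Generator,
    t: np.ndarray,
    intervals: list[tuple[float, float]],
    phasic_gain: float,
    noise_sd: float,
    task_duration_s: float,
) -> np.ndarray:
    """Galvanic resistance channel (reciprocal of conductance in microsiemens)."""
    base = rng.uniform(1.5, 3.0)
    slope = rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 0.6) / task_duration_s
    tonic = base + slope * t
    tonic += 0.03 * np.sin(2 * np.pi * t / task_duration_s + rng.uniform(0, 2 * np.pi))
    phasic = np.zeros_like(t)
    tau_rise, tau_decay = 0.3, 2.0
    for start, _ in intervals:
        onset = max(0.0, start - rng.uniform(0.0, 2.0))
        dt = t - onset
        shape = np.where(
            dt > 0, np.exp(-dt / tau_decay) - np.exp(-dt / tau_rise), 0.0
        )
        peak = shape.max()
        if peak > 0:
            phasic += phasic_gain * shape / peak
    conductance = tonic + phasic + rng.normal(0, noise_sd, t.size)
    conductance = np.clip(conductance, 0.2, None)
    return (1.0 / conductance)[np.newaxis, :]


def subject_profile(
    params: CohortParams, subject_index: int
) -> tuple[float, float, str]:
    """The per-subject draws shared across that subject's tasks:
    (gait frequency Hz, freeze frequency Hz, wrist FOG style)."""
    rng = np.random.default_rng([int(params.seed) % (2**31), subject_index])
    gait_hz = rng.uniform(*params.gait_freq_range_hz)
    freeze_hz = rng.uniform(*params.freeze_freq_range_hz)
    wrist_style = "attenuate" if rng.random() < 0.5 else "tremble"
    return gait_hz, freeze_hz, wrist_style


def simulate_subject(
    params: CohortParams, subject_index: int
) -> tuple[dict[str, Recording], AnnotationSet]:
    """Simulate all tasks of one subject.

    Per-subject gait and freeze frequencies (and the wrist FOG style —
    attenuated arm swing vs. trembling, reflecting the heterogeneity of upper
    limb behaviour during FOG) are drawn once and shared across that subject's
    tasks. Fully reproducible given ``(params.seed, subject_index)``.
    """
    params.validate()
    if not 0 <= subject_index < params.n_subjects:
        raise ValueError("subject_index out of range")
    rng = np.random.default_rng([int(params.seed) % (2**31), subject_index])
    subject_id = f"S{subject_index + 1:02d}"
    gait_hz = rng.uniform(*params.gait_freq_range_hz)
    freeze_hz = rng.uniform(*params.freeze_freq_range_hz)
    wrist_style = "attenuate" if rng.random() < 0.5 else "tremble"

    recordings: dict[str, Recording] = {}
    episodes: list[Episode] = []
    for task_index in range(params.tasks_per_subject):
        task_id = f"T{task_index + 1}"
        intervals = sample_episode_intervals(rng, params)
        episodes.extend(
            Episode(subject_id, task_id, a, b) for a, b in intervals
        )
        modalities: dict[str, ModalityData] = {}

        fs = NATIVE_FS["tibia_acc"]
        t = np.arange(int(round(params.task_duration_s * fs))) / fs
        fog = _regime_mask(t.size, fs, intervals)
        for name, walk_amps, fog_scale in (
            ("tibia_acc", (1.0, 0.5, 0.25), 1.0),
            ("tibia_gyro", (1.0, 0.4, 0.2), 1.0),
        ):
            samples = _inertial_modality(
                rng, t, fog, gait_hz, freeze_hz, walk_amps,
                fog_scale * params.fog_amplitude_ratio,
                params.noise_sd["inertial"],
            )
            modalities[name] = ModalityData(["x", "y", "z"], fs, samples)
        for name in ("wrist_acc", "wrist_gyro"):
            samples = _inertial_modality(
                rng, t, fog, gait_hz, freeze_hz, (0.8, 0.2),
                0.5 * params.fog_amplitude_ratio,
                params.noise_sd["inertial"], fog_style=wrist_style,
            )
            modalities[name] = ModalityData(["x", "y", "z"], fs, samples)

        fs_eeg = NATIVE_FS["eeg"]
        t_eeg = np.arange(int(round(params.task_duration_s * fs_eeg))) / fs_eeg
        fog_eeg = _regime_mask(t_eeg.size, fs_eeg, intervals)
        modalities["eeg"] = ModalityData(
            list(EEG_ELECTRODES),
            fs_eeg,
            _eeg_modality(
                rng, t_eeg, fog_eeg, params.eeg_fog_band_shift,
                params.noise_sd["eeg"],
            ),
        )

        fs_sc = NATIVE_FS["sc"]
        t_sc = np.arange(int(round(params.task_duration_s * fs_sc))) / fs_sc
        modalities["sc"] = ModalityData(
            ["sc"],
            fs_sc,
            _sc_modality(
                rng, t_sc, intervals, params.sc_phasic_gain,
                params.noise_sd["sc"], params.task_duration_s,
            ),
        )
        recordings[task_id] = Recording(subject_id, task_id, modalities)

    return recordings, AnnotationSet(episodes)


def simulate_cohort(
    params: CohortParams,
) -> tuple[list[Recording], AnnotationSet]:
    """Simulate the whole cohort: ``n_subjects x tasks_per_subject`` recordings."""
    params.validate()
    recordings: list[Recording] = []
    episodes: list[Episode] = []
    for i in range(params.n_subjects):
        recs, anns = simulate_subject(params, i)
        recordings.extend(recs.values())
        episodes.extend(anns.episodes)
    return recordings, AnnotationSet(episodes)


__all__ = [
    "CohortParams",
    "EEG_ELECTRODES",
    "OSCILLATOR_SITES",
    "NATIVE_FS",
    "sample_episode_intervals",
    "simulate_subject",
    "simulate_cohort",
]
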