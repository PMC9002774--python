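"""Signal conditioning: standardization, filtering, montage, and resampling.

All filters are applied zero-phase (forward-backward), because the analysis is
offline and window labels must stay aligned with the video-derived episode
annotations; causal filtering would shift signal content against the labels.

Per-modality pipeline (order: standardize -> filter -> resample to 500 Hz):

* inertial: z-score, 0.5-16 Hz band-pass (4th-order Butterworth high-pass +
  5th-order Butterworth low-pass);
* EEG: longitudinal bipolar montage (18 derivations), z-score per derivation,
  1.6-30 Hz band-pass (5th-order high-pass + 6th-order low-pass Chebyshev
  type I, 0.1 dB passband ripple);
* skin conductance: reciprocal of galvanic resistance, 2 Hz 5th-order
  Butterworth low-pass, suppression of rapid transients by a centered moving
  average, then a phasic/tonic split: SCR = 0.5 Hz high-pass of the filtered
  conductance, SCL = SC - SCR. Conductance is deliberately *not* z-scored —
  its features rely on physical phasic/tonic morphology (e.g. the tonic
  slope), which standardization would destroy.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .types import ModalityData, Recording

TARGET_FS = 500.0

#: Default 18-pair longitudinal bipolar montage over the available electrodes:
#: temporal chains, parasagittal chains, midline, and fronto-central /
#: centro-parietal derivations. The montage is configurable; results should be
#: reported together with the montage used.
DEFAULT_MONTAGE: tuple[tuple[str, str], ...] = (
    ("FP1", "F7"), ("F7", "P7"), ("P7", "O1"),
    ("FP2", "F8"), ("F8", "P8"), ("P8", "O2"),
    ("FP1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("FP2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("Fz", "Cz"), ("Cz", "Pz"),
    ("FC1", "CP1"), ("FC2", "CP2"),
)


class DegenerateSignalError(ValueError):
    """Raised for signals a stage cannot meaningfully process (e.g. constant)."""


def zscore_standardize(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit (population) standard deviation."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to standardize")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    sd = x.std()
    if sd == 0:
        raise DegenerateSignalError("zero-variance channel cannot be standardized")
    return (x - x.mean()) / sd


def resample_to_500hz(x: np.ndarray, fs_in: float) -> np.ndarray:
    """Band-limited (polyphase) resampling to the common 500 Hz analysis rate.

    Exact rational rate ratios (e.g. 100->500, 1000->500) make the polyphase
    method both alias-free and exactly length-predictable.
    """
    if not fs_in > 0:
        raise ValueError("fs_in must be positive")
    x = np.asarray(x, dtype=float)
    if fs_in == TARGET_FS:
        return x
    ratio = Fraction(TARGET_FS / fs_in).limit_denominator(10_000)
    return sps.resample_poly(x, ratio.numerator, ratio.denominator, axis=-1)


def _check_cutoffs(fs: float, *cutoffs: float) -> None:
    for c in cutoffs:
        if c >= fs / 2:
            raise ValueError(f"cutoff {c} Hz is at or above Nyquist ({fs / 2} Hz)")


def filter_inertial(x: np.ndarray, fs: float) -> np.ndarray:
    """0.5-16 Hz zero-phase Butterworth band-pass (4th-order HP, 5th-order LP)."""
    _check_cutoffs(fs, 0.5, 16.0)
    hp = sps.butter(4, 0.5, "highpass", fs=fs, output="sos")
    lp = sps.butter(5, 16.0, "lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(lp, sps.sosfiltfilt(hp, x, axis=-1), axis=-1)


def filter_eeg(x: np.ndarray, fs: float, ripple_db: float = 0.1) -> np.ndarray:
    """1.6-30 Hz zero-phase Chebyshev type-I band-pass (5th HP, 6th LP).

    A small passband ripple is used because forward-backward application
    squares the magnitude response, doubling any ripple loss.
    """
    _check_cutoffs(fs, 1.6, 30.0)
    hp = sps.cheby1(5, ripple_db, 1.6, "highpass", fs=fs, output="sos")
    lp = sps.cheby1(6, ripple_db, 30.0, "lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(lp, sps.sosfiltfilt(hp, x, axis=-1), axis=-1)


def make_bipolar_montage(
    eeg: ModalityData,
    montage: tuple[tuple[str, str], ...] = DEFAULT_MONTAGE,
) -> ModalityData:
    """Longitudinal bipolar derivation: each output channel is A - B.

    Differencing adjacent electrodes rejects common-mode activity and yields
    more spatially selective channels.
    """
    missing = sorted(
        {e for pair in montage for e in pair} - set(eeg.channel_names)
    )
    if missing:
        raise KeyError(f"montage references absent electrodes: {missing}")
    rows = [eeg.channel(a) - eeg.channel(b) for a, b in montage]
    names = [f"{a}-{b}" for a, b in montage]
    return ModalityData(names, eeg.fs, np.vstack(rows))


def resistance_to_conductance(resistance: np.ndarray) -> np.ndarray:
    """Element-wise reciprocal: galvanic resistance -> skin conductance."""
    resistance = np.asarray(resistance, dtype=float)
    if np.any(resistance <= 0):
        raise ValueError("resistance values must be strictly positive")
    return 1.0 / resistance


@dataclass
class SCComponents:
    """Filtered skin conductance and its phasic (SCR) / tonic (SCL) split.

    The split is additive by construction: ``scr + scl == sc_filtered``.
    """

    sc_filtered: np.ndarray
    scr: np.ndarray
    scl: np.ndarray
    fs: float


def detect_transients(
    x: np.ndarray, fs: float, k: float = 5.0, max_span_s: float = 0.5
) -> list[tuple[int, int]]:
    """Flag brief artefact transients: sample-to-sample jumps exceeding ``k``
    times the robust (MAD) first-difference scale, lasting under ``max_span_s``.
    """
    d = np.abs(np.diff(x))
    scale = np.median(np.abs(d - np.median(d))) * 1.4826
    if scale == 0:
        return []
    hot = np.flatnonzero(d > k * scale)
    spans: list[tuple[int, int]] = []
    if hot.size == 0:
        return spans
    start = prev = hot[0]
    for i in list(hot[1:]) + [None]:  # type: ignore[list-item]
        if i is not None and i <= prev + int(0.05 * fs):
            prev = i
            continue
        lo, hi = int(start), int(prev) + 2
        if (hi - lo) / fs < max_span_s:
            spans.append((lo, hi))
        if i is None:
            break
        start = prev = i
    return spans


def sc_decompose(
    sc: np.ndarray,
    fs: float,
    transient_mask: list[tuple[float, float]] | None = None,
    smoothing_window_s: float = 4.0,
) -> SCComponents:
    """Filter conductance and split it into phasic (SCR) and tonic (SCL) parts.

    Steps: 2 Hz 5th-order Butterworth low-pass (zero-phase); declared or
    detected transient spans replaced by a centered moving average
    (window 3-6 s, default 4 s); SCR = 0.5 Hz 5th-order Butterworth high-pass
    of the result; SCL = filtered SC - SCR.
    """
    sc = np.asarray(sc, dtype=float)
    if sc.size == 0:
        raise ValueError("empty conductance signal")
    lp = sps.butter(5, 2.0, "lowpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(lp, sc)

    if transient_mask is None:
        spans = detect_transients(filtered, fs)
    else:
        spans = [(int(a * fs), int(b * fs)) for a, b in transient_mask]
    if spans:
        win = max(1, int(round(smoothing_window_s * fs)))
        kernel = np.ones(win) / win
        smoothed = np.convolve(
            np.pad(filtered, win // 2, mode="edge"), kernel, mode="same"
        )[win // 2 : win // 2 + filtered.size]
        for lo, hi in spans:
            filtered[lo:hi] = smoothed[lo:hi]

    hp = sps.butter(5, 0.5, "highpass", fs=fs, output="sos")
    scr = sps.sosfiltfilt(hp, filtered)
    scl = filtered - scr
    return SCComponents(filtered, scr, scl, fs)


def preprocess_recording(
    recording: Recording,
    montage: tuple[tuple[str, str], ...] = DEFAULT_MONTAGE,
) -> Recording:
    """Run the full conditioning pipeline; every output modality is at 500 Hz.

    The ``sc`` modality is replaced by three channels — ``sc_filtered``,
    ``scr`` and ``scl`` — carrying the filtered conductance and its split.
    """
    out: dict[str, ModalityData] = {}
    for name, mod in recording.modalities.items():
        if name == "eeg":
            bipolar = make_bipolar_montage(mod, montage)
            rows = [
                resample_to_500hz(filter_eeg(zscore_standardize(ch), mod.fs), mod.fs)
                for ch in bipolar.samples
            ]
            out[name] = ModalityData(bipolar.channel_names, TARGET_FS, np.vstack(rows))
        elif name == "sc":
            conductance = resistance_to_conductance(mod.samples[0])
            comps = sc_decompose(conductance, mod.fs)
            rows = [
                resample_to_500hz(comps.sc_filtered, mod.fs),
                resample_to_500hz(comps.scr, mod.fs),
                resample_to_500hz(comps.scl, mod.fs),
            ]
            out[name] = ModalityData(
                ["sc_filtered", "scr", "scl"], TARGET_FS, np.vstack(rows)
            )
        else:
            rows = [
                resample_to_500hz(
                    filter_inertial(zscore_standardize(ch), mod.fs), mod.fs
                )
                for ch in mod.samples
            ]
            out[name] = ModalityData(list(mod.channel_names), TARGET_FS, np.vstack(rows))
    return Recording(recording.subject_id, recording.task_id, out)


__all__ = [
    "TARGET_FS",
    "DEFAULT_MONTAGE",
    "DegenerateSignalError",
    "SCComponents",
    "zscore_standardize",
    "resample_to_500hz",
    "filter_inertial",
    "filter_eeg",
    "make_bipolar_montage",
    "resistance_to_conductance",
    "detect_transients",
    "sc_decompose",
    "preprocess_recording",
]
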