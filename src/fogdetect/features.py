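"""Windowed feature battery with a calibrated, auditable column registry.

Per 3-s window the battery yields exactly:

* 186 tibial inertial columns — 17 frequency + 14 time features for each of
  the 3 axes of the accelerometer and the gyroscope;
* 168 wrist inertial columns — per sensor (acc, gyro): 24 frequency + 3 time
  features on the Euclidean signal magnitude and 7 frequency + 12 time
  features on each component;
* 1107 EEG columns — 16 frequency + 3 time features per bipolar channel (18
  channels) plus magnitude squared coherence averaged within the 5 EEG bands
  for all 153 channel pairs;
* 39 skin-conductance columns — 10 frequency + 9 time features of the phasic
  component, 8 time features of each of its first two derivatives, and 3
  frequency features plus the least-squares slope of the tonic component.

Every column is registered with its sensor, channel (or channel pair), domain
and band, and the registry can be exported as a machine-readable feature
dictionary so the calibration of the per-sensor totals is auditable.

Features are range-normalized onto [0, 1] with minima/maxima fitted on
training rows only; held-out rows are transformed with the training statistics
and clipped, so no information from a test subject leaks into its fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import spectral
from .spectral import (
    EEG_BANDS,
    FREEZE_BAND,
    LOCOMOTION_BAND,
    SpectralEstimate,
    band_msc,
    psd_estimate,
)
from .types import Recording, WindowSet
from .windowing import window_slice

SENSOR_GROUPS = ("tibia", "wrist", "eeg", "sc")

#: Contracted per-sensor column totals.
EXPECTED_COUNTS = {"tibia": 186, "wrist": 168, "eeg": 1107, "sc": 39}

PEAK_PROMINENCE_FACTOR = 0.1  # x window standard deviation


@dataclass
class FeatureMatrix:
    """Windows x named features, with per-column provenance."""

    data: pd.DataFrame
    registry: list[dict] = field(default_factory=list)
    windows: WindowSet | None = None

    @property
    def labels(self) -> np.ndarray:
        if self.windows is None:
            raise ValueError("no windows attached")
        return self.windows.labels

    def sensor_columns(self, sensor: str) -> list[str]:
        return [r["name"] for r in self.registry if r["sensor"] == sensor]

    def feature_dictionary(self) -> pd.DataFrame:
        return pd.DataFrame(self.registry)


# ---------------------------------------------------------------------------
# low-level batched statistics (rows = windows)


def _time_stats(W: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    dt = 1.0 / fs
    duration = W.shape[1] * dt
    signs = np.sign(W)
    n_zc = np.count_nonzero(np.diff(signs, axis=1) != 0, axis=1).astype(float)
    stats = {
        "rms": np.sqrt((W**2).mean(axis=1)),
        "mean": W.mean(axis=1),
        "std": W.std(axis=1),
        "n_zero_crossings": n_zc,
        "zero_crossing_rate": n_zc / duration,
        "energy": (W**2).sum(axis=1),
        "max_amplitude": W.max(axis=1),
        "min_amplitude": W.min(axis=1),
        "range": W.max(axis=1) - W.min(axis=1),
        "integral": np.trapezoid(W, dx=dt, axis=1),
        "median": np.median(W, axis=1),
    }
    return stats


def _peak_stats(W: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """Local-maximum peaks with prominence >= 0.1 x window std.

    Windows without peaks report 0 for count, distance and height.
    """
    n = W.shape[0]
    n_peaks = np.zeros(n)
    mean_dist = np.zeros(n)
    mean_height = np.zeros(n)
    for i, row in enumerate(W):
        sd = row.std()
        if sd == 0:
            continue
        peaks, props = find_peaks(row, prominence=PEAK_PROMINENCE_FACTOR * sd)
        n_peaks[i] = peaks.size
        if peaks.size:
            mean_height[i] = row[peaks].mean()
        if peaks.size >= 2:
            mean_dist[i] = np.diff(peaks).mean() / fs
    return {
        "n_peaks": n_peaks,
        "mean_peak_distance": mean_dist,
        "mean_peak_height": mean_height,
    }


def _local_extrema_counts(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = W.shape[0]
    n_min = np.zeros(n)
    n_max = np.zeros(n)
    for i, row in enumerate(W):
        sd = row.std()
        if sd == 0:
            continue
        prom = PEAK_PROMINENCE_FACTOR * sd
        n_max[i] = find_peaks(row, prominence=prom)[0].size
        n_min[i] = find_peaks(-row, prominence=prom)[0].size
    return n_min, n_max


def _band_power_std(spec: SpectralEstimate, lo: float, hi: float) -> np.ndarray:
    sel = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    return np.atleast_2d(spec.power)[:, sel].std(axis=1)


def _freq_stats(spec: SpectralEstimate) -> dict[str, np.ndarray]:
    out = spectral.spectral_moments(spec)
    out["energy_psd"] = (np.atleast_2d(spec.power) ** 2).sum(axis=1) * spec.df
    out["locomotion_band_power"] = spectral.band_power(spec, *LOCOMOTION_BAND)
    out["freeze_band_power"] = spectral.band_power(spec, *FREEZE_BAND)
    out["locomotion_band_power_std"] = _band_power_std(spec, *LOCOMOTION_BAND)
    out["freeze_band_power_std"] = _band_power_std(spec, *FREEZE_BAND)
    out["freeze_index"] = spectral.freeze_index(spec)
    out["freeze_ratio"] = spectral.freeze_ratio(spec)
    return {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in out.items()}


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = (A * B).sum(axis=1)
    den = np.sqrt((A**2).sum(axis=1) * (B**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def _window_matrix(x: np.ndarray, windows: WindowSet, fs: float) -> np.ndarray:
    return np.stack([x[window_slice(w, fs)] for w in windows.windows])


# ---------------------------------------------------------------------------
# per-sensor extraction

TIBIA_FREQ = (
    "total_power", "mean_power", "max_power", "std_power",
    "locomotion_band_power", "freeze_band_power",
    "locomotion_band_power_std", "freeze_band_power_std",
    "freeze_index", "freeze_ratio", "skewness_psd", "kurtosis_psd",
    "energy_psd", "entropy_psd", "dominant_frequency", "mean_frequency",
    "median_frequency",
)
TIBIA_TIME = (
    "rms", "mean", "std", "n_zero_crossings", "zero_crossing_rate",
    "n_peaks", "mean_peak_distance", "mean_peak_height", "energy",
    "max_amplitude", "min_amplitude", "range", "integral",
    "axes_correlation",
)
#: Axis pairing used for the per-channel axes-correlation slot.
AXES_PAIR = {"x": ("x", "y"), "y": ("y", "z"), "z": ("z", "x")}

WRIST_MAG_FREQ = (
    ("total_power", None), ("mean_power", None), ("std_power", None),
    ("max_power", None),
    *[(f"power_{lo}_{lo + 1}", (float(lo), float(lo + 1))) for lo in range(16)],
    ("locomotion_band_power", LOCOMOTION_BAND),
    ("freeze_band_power", FREEZE_BAND),
    ("power_9_12", (9.0, 12.0)),
    ("power_13_16", (13.0, 16.0)),
)
WRIST_MAG_TIME = ("rms", "mean", "std")
WRIST_COMP_FREQ = (
    "total_power", "mean_power", "std_power", "max_power",
    "dominant_frequency", "mean_frequency", "median_frequency",
)
WRIST_COMP_TIME = (
    "rms", "mean", "std", "n_zero_crossings", "zero_crossing_rate",
    "n_peaks", "mean_peak_distance", "mean_peak_height", "energy",
    "max_amplitude", "min_amplitude", "range",
)

EEG_FREQ = (
    "total_power", "mean_power", "std_power", "max_power",
    "skewness_psd", "kurtosis_psd", "energy_psd", "entropy_psd",
    "dominant_frequency", "mean_frequency", "median_frequency",
    *[f"{b}_band_power" for b in EEG_BANDS],
)
EEG_TIME = ("rms", "mean", "std")

SC_PHASIC_FREQ = (
    "total_power", "mean_power", "std_power", "skewness_psd",
    "kurtosis_psd", "energy_psd", "entropy_psd", "dominant_frequency",
    "median_frequency", "mean_frequency",
)
SC_PHASIC_TIME = (
    "rms", "mean", "std", "median", "min_amplitude", "max_amplitude",
    "range", "n_local_min", "n_local_max",
)
SC_DER_TIME = (
    "mean", "median", "std", "min_amplitude", "max_amplitude", "range",
    "n_local_min", "n_local_max",
)
SC_TONIC_FREQ = ("total_power", "mean_frequency", "median_frequency")


def _register(
    registry: list[dict], columns: dict[str, np.ndarray],
    name: str, values: np.ndarray, sensor: str, channel: str,
    domain: str, band: str | None = None,
) -> None:
    if name in columns:
        raise ValueError(f"duplicate feature column {name!r}")
    columns[name] = values
    registry.append(
        {
            "name": name,
            "sensor": sensor,
            "channel": channel,
            "domain": domain,
            "band": band if band is not None else "",
        }
    )


def extract_tibia(
    recording: Recording, windows: WindowSet,
    columns: dict[str, np.ndarray], registry: list[dict],
) -> None:
    """186 columns: full frequency + time battery per tibial axis/sensor."""
    for modality in ("tibia_acc", "tibia_gyro"):
        mod = recording.modalities[modality]
        fs = mod.fs
        mats = {
            ax: _window_matrix(mod.channel(ax), windows, fs) for ax in ("x", "y", "z")
        }
        for ax in ("x", "y", "z"):
            W = mats[ax]
            spec = psd_estimate(W, fs=fs)
            fstats = _freq_stats(spec)
            tstats = {**_time_stats(W, fs), **_peak_stats(W, fs)}
            a, b = AXES_PAIR[ax]
            tstats["axes_correlation"] = _rowwise_corr(mats[a], mats[b])
            for name in TIBIA_FREQ:
                _register(
                    registry, columns, f"{modality}|{ax}|{name}", fstats[name],
                    "tibia", f"{modality}:{ax}", "frequency",
                )
            for name in TIBIA_TIME:
                _register(
                    registry, columns, f"{modality}|{ax}|{name}", tstats[name],
                    "tibia", f"{modality}:{ax}", "time",
                )


def extract_wrist(
    recording: Recording, windows: WindowSet,
    columns: dict[str, np.ndarray], registry: list[dict],
) -> None:
    """168 columns: magnitude-stream battery + per-component battery."""
    for modality in ("wrist_acc", "wrist_gyro"):
        mod = recording.modalities[modality]
        fs = mod.fs
        mats = {
            ax: _window_matrix(mod.channel(ax), windows, fs) for ax in ("x", "y", "z")
        }
        mag = np.sqrt(mats["x"] ** 2 + mats["y"] ** 2 + mats["z"] ** 2)
        spec = psd_estimate(mag, fs=fs)
        fstats = _freq_stats(spec)
        tstats = _time_stats(mag, fs)
        for name, band in WRIST_MAG_FREQ:
            values = (
                np.atleast_1d(np.asarray(spectral.band_power(spec, *band)))
                if band is not None
                else fstats[name]
            )
            _register(
                registry, columns, f"{modality}|mag|{name}", values,
                "wrist", f"{modality}:mag", "frequency",
                band=f"{band[0]}-{band[1]}Hz" if band else None,
            )
        for name in WRIST_MAG_TIME:
            _register(
                registry, columns, f"{modality}|mag|{name}", tstats[name],
                "wrist", f"{modality}:mag", "time",
            )
        for ax in ("x", "y", "z"):
            W = mats[ax]
            spec = psd_estimate(W, fs=fs)
            fstats = _freq_stats(spec)
            tstats = {**_time_stats(W, fs), **_peak_stats(W, fs)}
            for name in WRIST_COMP_FREQ:
                _register(
                    registry, columns, f"{modality}|{ax}|{name}", fstats[name],
                    "wrist", f"{modality}:{ax}", "frequency",
                )
            for name in WRIST_COMP_TIME:
                _register(
                    registry, columns, f"{modality}|{ax}|{name}", tstats[name],
                    "wrist", f"{modality}:{ax}", "time",
                )


def extract_eeg(
    recording: Recording, windows: WindowSet,
    columns: dict[str, np.ndarray], registry: list[dict],
) -> None:
    """1107 columns: per-channel battery + band-averaged pairwise coherence."""
    mod = recording.modalities["eeg"]
    if mod.samples.shape[0] != 18:
        raise ValueError(
            f"EEG feature extraction expects 18 bipolar channels, "
            f"got {mod.samples.shape[0]}"
        )
    fs = mod.fs
    for ch in mod.channel_names:
        W = _window_matrix(mod.channel(ch), windows, fs)
        spec = psd_estimate(W, fs=fs)
        fstats = _freq_stats(spec)
        for band, (lo, hi) in EEG_BANDS.items():
            fstats[f"{band}_band_power"] = np.atleast_1d(
                np.asarray(spectral.band_power(spec, lo, hi))
            )
        tstats = _time_stats(W, fs)
        for name in EEG_FREQ:
            _register(
                registry, columns, f"eeg|{ch}|{name}", fstats[name],
                "eeg", ch, "frequency",
                band=name.split("_band_power")[0] if "band_power" in name else None,
            )
        for name in EEG_TIME:
            _register(
                registry, columns, f"eeg|{ch}|{name}", tstats[name],
                "eeg", ch, "time",
            )
    # magnitude squared coherence per pair, averaged per band
    n_win = len(windows)
    pair_idx = None
    msc_acc: dict[str, list[np.ndarray]] = {b: [] for b in EEG_BANDS}
    for w in windows.windows:
        seg = mod.samples[:, window_slice(w, fs)]
        pair_idx, bands = band_msc(seg, fs=fs)
        for b in EEG_BANDS:
            msc_acc[b].append(bands[b])
    for b in EEG_BANDS:
        stacked = (
            np.vstack(msc_acc[b]) if n_win else np.empty((0, 153))
        )
        if pair_idx is None:
            pair_idx = np.column_stack(np.triu_indices(18, k=1))
        for col, (i, j) in enumerate(pair_idx):
            a, c = mod.channel_names[i], mod.channel_names[j]
            _register(
                registry, columns, f"eeg|msc|{a}&{c}|{b}",
                stacked[:, col] if n_win else np.empty(0),
                "eeg", f"{a}&{c}", "frequency", band=b,
            )


def extract_sc(
    recording: Recording, windows: WindowSet,
    columns: dict[str, np.ndarray], registry: list[dict],
) -> None:
    """39 columns from the phasic component, its derivatives, and the tonic."""
    mod = recording.modalities["sc"]
    fs = mod.fs
    phasic = _window_matrix(mod.channel("scr"), windows, fs)
    tonic = _window_matrix(mod.channel("scl"), windows, fs)

    spec = psd_estimate(phasic, fs=fs)
    fstats = _freq_stats(spec)
    tstats = _time_stats(phasic, fs)
    n_min, n_max = _local_extrema_counts(phasic)
    tstats["n_local_min"], tstats["n_local_max"] = n_min, n_max
    for name in SC_PHASIC_FREQ:
        _register(
            registry, columns, f"sc|phasic|{name}", fstats[name],
            "sc", "phasic", "frequency",
        )
    for name in SC_PHASIC_TIME:
        _register(
            registry, columns, f"sc|phasic|{name}", tstats[name],
            "sc", "phasic", "time",
        )

    dt = 1.0 / fs
    for label, W in (
        ("der1", np.gradient(phasic, dt, axis=1)),
        ("der2", np.gradient(np.gradient(phasic, dt, axis=1), dt, axis=1)),
    ):
        dstats = _time_stats(W, fs)
        n_min, n_max = _local_extrema_counts(W)
        dstats["n_local_min"], dstats["n_local_max"] = n_min, n_max
        for name in SC_DER_TIME:
            _register(
                registry, columns, f"sc|{label}|{name}", dstats[name],
                "sc", label, "time",
            )

    spec_t = psd_estimate(tonic, fs=fs)
    fstats_t = _freq_stats(spec_t)
    for name in SC_TONIC_FREQ:
        _register(
            registry, columns, f"sc|tonic|{name}", fstats_t[name],
            "sc", "tonic", "frequency",
        )
    # least-squares slope of the tonic level across the window (uS/s)
    t = np.arange(tonic.shape[1]) * dt
    tc = t - t.mean()
    slope = (tonic - tonic.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    _register(registry, columns, "sc|tonic|slope", slope, "sc", "tonic", "time")


_EXTRACTORS = {
    "tibia": extract_tibia,
    "wrist": extract_wrist,
    "eeg": extract_eeg,
    "sc": extract_sc,
}


def extract_features(
    recording: Recording,
    windows: WindowSet,
    sensors: tuple[str, ...] = SENSOR_GROUPS,
) -> FeatureMatrix:
    """Extract the battery for one recording over its windows.

    ``sensors`` restricts extraction to a subset of sensor groups (e.g. only
    the tibial inertial sensors for a minimal single-sensor configuration).
    """
    unknown = set(sensors) - set(SENSOR_GROUPS)
    if unknown:
        raise ValueError(f"unknown sensor groups: {sorted(unknown)}")
    columns: dict[str, np.ndarray] = {}
    registry: list[dict] = []
    for sensor in SENSOR_GROUPS:
        if sensor in sensors:
            _EXTRACTORS[sensor](recording, windows, columns, registry)
    df = pd.DataFrame(columns, index=range(len(windows)))
    fm = FeatureMatrix(df, registry, windows)
    for sensor in sensors:
        got = len(fm.sensor_columns(sensor))
        if got != EXPECTED_COUNTS[sensor]:
            raise AssertionError(
                f"feature-count contract violated for {sensor}: "
                f"{got} != {EXPECTED_COUNTS[sensor]}"
            )
    return fm


def concat_feature_matrices(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-recording matrices (same columns) into a cohort matrix."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    base_cols = list(matrices[0].data.columns)
    for m in matrices[1:]:
        if list(m.data.columns) != base_cols:
            raise ValueError("feature matrices have mismatched columns")
    data = pd.concat([m.data for m in matrices], ignore_index=True)
    windows = matrices[0].windows
    for m in matrices[1:]:
        windows = windows + m.windows
    return FeatureMatrix(data, matrices[0].registry, windows)


class RangeNormalizer:
    """Min-max normalization onto [0, 1], fitted on training rows only.

    Held-out rows are transformed with the training minima/maxima and clipped
    into [0, 1] (so out-of-range test values, including +inf sentinels from
    degenerate band ratios, saturate rather than leak or explode). Columns
    constant on the fitting rows are dropped with a warning.
    """

    def __init__(self) -> None:
        self.mins: pd.Series | None = None
        self.maxs: pd.Series | None = None
        self.columns: list[str] = []

    def fit(self, df: pd.DataFrame) -> "RangeNormalizer":
        finite = df.where(np.isfinite(df))
        mins = finite.min(axis=0)
        maxs = finite.max(axis=0)
        keep = (maxs - mins) > 0
        dropped = [c for c, k in keep.items() if not k]
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} constant feature column(s)",
                stacklevel=2,
            )
        self.columns = [c for c, k in keep.items() if k]
        self.mins = mins[self.columns]
        self.maxs = maxs[self.columns]
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.mins is None or self.maxs is None:
            raise RuntimeError("normalizer not fitted")
        out = (df[self.columns] - self.mins) / (self.maxs - self.mins)
        return out.clip(0.0, 1.0)

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


def range_normalize(
    matrix: FeatureMatrix, fit_rows: np.ndarray | None = None
) -> tuple[FeatureMatrix, RangeNormalizer]:
    """Normalize a feature matrix; ``fit_rows`` restricts the statistics to
    training rows (all rows when omitted)."""
    norm = RangeNormalizer()
    fit_df = matrix.data if fit_rows is None else matrix.data.iloc[fit_rows]
    norm.fit(fit_df)
    data = norm.transform(matrix.data)
    registry = [r for r in matrix.registry if r["name"] in set(norm.columns)]
    return FeatureMatrix(data, registry, matrix.windows), norm


__all__ = [
    "SENSOR_GROUPS",
    "EXPECTED_COUNTS",
    "FeatureMatrix",
    "extract_features",
    "extract_tibia",
    "extract_wrist",
    "extract_eeg",
    "extract_sc",
    "concat_feature_matrices",
    "RangeNormalizer",
    "range_normalize",
]
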