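"""Welch spectra and the band-power statistics built on them.

The power spectral density underlying every frequency-domain feature is a
Welch average of 1-s Hann-tapered segments with 50 % overlap, giving 1 Hz
resolution on 3-s windows at 500 Hz. The two clinically meaningful bands for
movement signals are the locomotion band (0.5-3 Hz, normal gait) and the
freeze band (3-8 Hz, trembling-in-place); their power ratio is the freeze
index, and the bounded variant P(3-8)/P(0.5-8) is the freeze ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

LOCOMOTION_BAND = (0.5, 3.0)
FREEZE_BAND = (3.0, 8.0)

#: EEG bands, bounded by the 1.6-30 Hz analysis filter.
EEG_BANDS = {
    "delta": (1.6, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta1": (13.0, 20.0),
    "beta2": (20.0, 30.0),
}


@dataclass
class SpectralEstimate:
    """A PSD on a frequency grid; ``power`` may be (..., n_freqs) batched."""

    frequencies: np.ndarray
    power: np.ndarray
    nperseg: int
    noverlap: int
    taper: str = "hann"

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def psd_estimate(
    x: np.ndarray, fs: float = 500.0, segment_s: float = 1.0
) -> SpectralEstimate:
    """Welch PSD: 1-s Hann segments, 50 % overlap. Accepts batched input
    (..., n_samples) and returns matching batched power."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * fs))
    if x.shape[-1] < max(256, nperseg // 2):
        raise ValueError(f"window too short for PSD ({x.shape[-1]} samples)")
    nperseg = min(nperseg, x.shape[-1])
    f, p = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant", axis=-1,
    )
    return SpectralEstimate(f, p, nperseg, nperseg // 2)


def band_power(spec: SpectralEstimate, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of the PSD over [lo, hi] Hz.

    Band edges falling between grid points are handled by linear
    interpolation of the PSD at the edge frequencies.
    """
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band [{lo}, {hi}]")
    f = spec.frequencies
    if hi > f[-1] + 1e-9:
        raise ValueError(f"band edge {hi} Hz beyond Nyquist {f[-1]} Hz")
    p = np.atleast_2d(spec.power)
    inside = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inside], [hi]))
    interp = np.vstack([np.interp(grid, f, row) for row in p])
    out = np.trapezoid(interp, grid, axis=-1)
    return out.reshape(spec.power.shape[:-1]) if spec.power.ndim > 1 else float(out[0])


def freeze_index(spec: SpectralEstimate) -> np.ndarray:
    """Freeze-band power over locomotion-band power; +inf when the
    denominator vanishes (flagged downstream by normalization clipping)."""
    num = np.asarray(band_power(spec, *FREEZE_BAND), dtype=float)
    den = np.asarray(band_power(spec, *LOCOMOTION_BAND), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return out if out.ndim else float(out)


def freeze_ratio(spec: SpectralEstimate) -> np.ndarray:
    """Bounded freeze-band fraction: P(3-8) / P(0.5-8), in [0, 1]."""
    num = np.asarray(band_power(spec, *FREEZE_BAND), dtype=float)
    den = np.asarray(
        band_power(spec, LOCOMOTION_BAND[0], FREEZE_BAND[1]), dtype=float
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    return out if out.ndim else float(out)


def spectral_moments(spec: SpectralEstimate) -> dict[str, np.ndarray]:
    """Shape statistics of the normalized spectral distribution.

    Returns dominant/mean/median frequency, skewness and excess kurtosis of
    the spectral distribution, Shannon entropy normalized to [0, 1] by
    log(n_bins), and total/mean/max/std of the PSD values.
    """
    f = spec.frequencies
    p = np.atleast_2d(spec.power)
    total = p.sum(axis=-1)
    if np.all(total <= 0):
        raise ValueError("all-zero spectrum has no spectral distribution")
    # a degenerate (all-zero) row inside a batch gets a uniform spectral
    # distribution: its moments are defined and finite, its powers stay 0
    zero = total <= 0
    w = np.where(
        zero[..., None], 1.0 / p.shape[-1], p / np.where(zero, 1.0, total)[..., None]
    )
    mean_f = (w * f).sum(axis=-1)
    var_f = (w * (f - mean_f[..., None]) ** 2).sum(axis=-1)
    sd_f = np.sqrt(var_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(
            sd_f > 0,
            (w * (f - mean_f[..., None]) ** 3).sum(axis=-1) / np.where(sd_f > 0, sd_f, 1) ** 3,
            0.0,
        )
        kurt = np.where(
            sd_f > 0,
            (w * (f - mean_f[..., None]) ** 4).sum(axis=-1) / np.where(sd_f > 0, sd_f, 1) ** 4 - 3.0,
            0.0,
        )
    cum = np.cumsum(w, axis=-1)
    median_f = f[np.argmax(cum >= 0.5, axis=-1)]
    dominant_f = f[np.argmax(p, axis=-1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), 0.0)
    entropy = -(w * logw).sum(axis=-1) / np.log(w.shape[-1])
    df = spec.df
    out = {
        "dominant_frequency": dominant_f,
        "mean_frequency": mean_f,
        "median_frequency": median_f,
        "skewness_psd": skew,
        "kurtosis_psd": kurt,
        "entropy_psd": entropy,
        "total_power": p.sum(axis=-1) * df,
        "mean_power": p.mean(axis=-1),
        "max_power": p.max(axis=-1),
        "std_power": p.std(axis=-1),
    }
    if spec.power.ndim == 1:
        out = {k: float(np.asarray(v).reshape(-1)[0]) for k, v in out.items()}
    return out


def band_msc(
    samples: np.ndarray, fs: float = 500.0, segment_s: float = 1.0
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Magnitude squared coherence for all channel pairs, averaged per band.

    ``samples`` is (n_channels, n_samples). Returns the pair index array of
    shape (n_pairs, 2) and, per EEG band, a vector of band-mean MSC values for
    each pair (upper-triangle order).
    """
    samples = np.asarray(samples, dtype=float)
    nch, n = samples.shape
    nperseg = min(int(round(segment_s * fs)), n)
    step = nperseg // 2
    starts = range(0, n - nperseg + 1, step)
    win = sps.get_window("hann", nperseg)
    segs = np.stack(
        [(samples[:, s : s + nperseg] - samples[:, s : s + nperseg].mean(axis=-1, keepdims=True)) * win
         for s in starts],
        axis=1,
    )  # (nch, nseg, nperseg)
    X = np.fft.rfft(segs, axis=-1)
    f = np.fft.rfftfreq(nperseg, 1.0 / fs)
    # cross-spectra averaged over segments: (nch, nch, nfreq)
    S = np.einsum("isf,jsf->ijf", X, np.conj(X)) / segs.shape[1]
    auto = np.real(np.einsum("iif->if", S))
    iu, ju = np.triu_indices(nch, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(S[iu, ju]) ** 2 / np.clip(auto[iu] * auto[ju], 1e-300, None)
    bands = {}
    for name, (lo, hi) in EEG_BANDS.items():
        sel = (f >= lo) & (f <= hi)
        bands[name] = msc[:, sel].mean(axis=-1)
    return np.column_stack([iu, ju]), bands


__all__ = [
    "LOCOMOTION_BAND",
    "FREEZE_BAND",
    "EEG_BANDS",
    "SpectralEstimate",
    "psd_estimate",
    "band_power",
    "freeze_index",
    "freeze_ratio",
    "spectral_moments",
    "band_msc",
]
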