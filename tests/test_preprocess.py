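"""Filtering, standardization, montage and resampling contracts."""

import numpy as np
import pytest

from fogdetect.preprocess import (
    DEFAULT_MONTAGE,
    DegenerateSignalError,
    filter_eeg,
    filter_inertial,
    make_bipolar_montage,
    resample_to_500hz,
    resistance_to_conductance,
    sc_decompose,
    zscore_standardize,
)
from fogdetect.spectral import psd_estimate
from fogdetect.types import ModalityData


def _amp(x):
    core = x[len(x) // 4 : -len(x) // 4]
    return (core.max() - core.min()) / 2


class TestZScore:
    def test_closed_form(self):
        out = zscore_standardize(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487])
        assert abs(out.mean()) < 1e-12 and abs(out.std() - 1) < 1e-12

    def test_idempotent(self):
        x = np.random.default_rng(0).standard_normal(1000)
        once = zscore_standardize(x)
        np.testing.assert_allclose(zscore_standardize(once), once, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            zscore_standardize(np.array([5.0, 5.0, 5.0]))


class TestResample:
    def test_upsample_length(self):
        assert resample_to_500hz(np.zeros(300), 100.0).size == 1500

    def test_identity_at_target_rate(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(resample_to_500hz(x, 500.0), x)

    def test_spectral_peak_preserved(self):
        t = np.arange(3000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = resample_to_500hz(x, 100.0)
        spec = psd_estimate(y, fs=500.0, segment_s=2.0)
        peak = spec.frequencies[np.argmax(spec.power)]
        assert abs(peak - 1.0) <= spec.df

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            resample_to_500hz(np.zeros(10), 0.0)


class TestInertialFilter:
    def test_passband_and_stopband(self):
        fs = 100.0
        t = np.arange(int(30 * fs)) / fs
        assert _amp(filter_inertial(np.sin(2 * np.pi * 2 * t), fs)) >= 0.95
        assert _amp(filter_inertial(np.sin(2 * np.pi * 40 * t), fs)) <= 0.05

    def test_dc_removed(self):
        fs = 100.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 3 * t)
        np.testing.assert_allclose(
            filter_inertial(x + 10.0, fs), filter_inertial(x, fs), atol=1e-3
        )

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            filter_inertial(np.zeros(100), 30.0)  # 16 Hz >= Nyquist 15 Hz


class TestEEGFilter:
    def test_passband_stopband_drift(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        assert _amp(filter_eeg(np.sin(2 * np.pi * 10 * t), fs)) >= 0.9
        assert _amp(filter_eeg(np.sin(2 * np.pi * 60 * t), fs)) <= 0.05
        # slow drift is removed to within 5% of its amplitude
        drift = 3.0 * np.sin(2 * np.pi * 0.2 * t)
        x = np.sin(2 * np.pi * 10 * t)
        diff = filter_eeg(x + drift, fs) - filter_eeg(x, fs)
        assert np.abs(diff[int(5 * fs) : -int(5 * fs)]).max() <= 0.05 * 3.0


def test_zero_phase_symmetric_pulse():
    """Forward-backward filtering leaves a symmetric pulse's peak in place."""
    fs = 500.0
    n = 4001
    center = n // 2
    t = (np.arange(n) - center) / fs
    pulse = np.exp(-(t**2) / (2 * 0.2**2))
    for filt in (filter_inertial, filter_eeg):
        out = filt(pulse, fs)
        assert abs(int(np.argmax(out)) - center) <= 1


class TestMontage:
    def _eeg(self, n=2000):
        rng = np.random.default_rng(4)
        from fogdetect.synth import EEG_ELECTRODES

        return ModalityData(
            list(EEG_ELECTRODES), 1000.0,
            rng.standard_normal((len(EEG_ELECTRODES), n)),
        )

    def test_exactly_18_channels(self):
        out = make_bipolar_montage(self._eeg())
        assert out.samples.shape[0] == 18
        assert out.channel_names[0] == "FP1-F7"

    def test_common_mode_rejection(self):
        eeg = self._eeg()
        common = np.sin(2 * np.pi * 7 * np.arange(eeg.n_samples) / eeg.fs)
        shifted = ModalityData(
            list(eeg.channel_names), eeg.fs, eeg.samples + common
        )
        out1 = make_bipolar_montage(eeg)
        out2 = make_bipolar_montage(shifted)
        np.testing.assert_allclose(out1.samples, out2.samples, atol=1e-12)

    def test_identical_pair_gives_zero(self):
        eeg = self._eeg()
        idx_a = eeg.channel_names.index("FP1")
        idx_b = eeg.channel_names.index("F7")
        eeg.samples[idx_b] = eeg.samples[idx_a]
        out = make_bipolar_montage(eeg)
        np.testing.assert_array_equal(out.samples[0], 0.0)

    def test_missing_electrode_reported(self):
        eeg = self._eeg()
        with pytest.raises(KeyError, match="XX"):
            make_bipolar_montage(eeg, (("FP1", "XX"),) + DEFAULT_MONTAGE[1:])

    def test_invariant_to_electrode_order(self):
        eeg = self._eeg()
        perm = np.random.default_rng(1).permutation(len(eeg.channel_names))
        shuffled = ModalityData(
            [eeg.channel_names[i] for i in perm], eeg.fs, eeg.samples[perm]
        )
        np.testing.assert_allclose(
            make_bipolar_montage(eeg).samples,
            make_bipolar_montage(shuffled).samples,
        )


class TestSkinConductance:
    def test_reciprocal_conversion(self):
        np.testing.assert_allclose(
            resistance_to_conductance(np.array([2.0, 4.0])), [0.5, 0.25]
        )
        x = np.array([0.7, 1.3, 2.9])
        np.testing.assert_allclose(
            resistance_to_conductance(resistance_to_conductance(x)), x
        )
        with pytest.raises(ValueError):
            resistance_to_conductance(np.array([1.0, 0.0]))

    def test_additive_decomposition(self):
        rng = np.random.default_rng(7)
        fs = 100.0
        t = np.arange(int(60 * fs)) / fs
        sc = 2.0 + 0.01 * t + 0.05 * rng.standard_normal(t.size)
        comps = sc_decompose(sc, fs)
        np.testing.assert_allclose(
            comps.scr + comps.scl, comps.sc_filtered, atol=1e-9
        )

    def test_constant_goes_to_tonic(self):
        fs = 100.0
        comps = sc_decompose(np.full(int(30 * fs), 2.5), fs)
        assert np.abs(comps.scr).max() < 1e-6
        np.testing.assert_allclose(
            comps.scl[int(5 * fs) : -int(5 * fs)], 2.5, atol=1e-6
        )

    def test_phasic_bump_lands_in_scr(self):
        """The energy of a fast exponential bump predominantly enters the
        phasic (SCR) component, while the slow ramp stays tonic.

        Note the split can never exceed ~75% for an exponential bump: the
        2-Hz low-pass confines the bump to [0, 2] Hz and the 0.5-Hz phasic
        high-pass then claims at most the [0.5, 2] Hz share of it.
        """
        fs = 100.0
        t = np.arange(int(120 * fs)) / fs
        ramp = 2.0 + 0.05 * np.sin(2 * np.pi * 0.05 * t)
        dt = np.clip(t - 60.0, 0.0, None)
        bump = np.where(
            t > 60.0, np.exp(-dt / 0.05) - np.exp(-dt / 0.02), 0.0
        )
        comps = sc_decompose(ramp + bump, fs)
        comps_base = sc_decompose(ramp, fs)
        scr_energy = np.sum((comps.scr - comps_base.scr) ** 2)
        scl_energy = np.sum((comps.scl - comps_base.scl) ** 2)
        assert scr_energy / (scr_energy + scl_energy) > 0.6
        # and the slow ramp itself stays out of the phasic component
        assert np.sum(comps_base.scr**2) < 0.01 * np.sum(
            (comps_base.scl - comps_base.scl.mean()) ** 2
        )

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            sc_decompose(np.array([]), 100.0)
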