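"""Spectral estimators, the feature battery and its count calibration."""

import numpy as np
import pandas as pd
import pytest

import fogdetect as fd
from fogdetect.features import (
    EXPECTED_COUNTS,
    RangeNormalizer,
    _time_stats,
    extract_features,
)
from fogdetect.selection import pointbiserial
from fogdetect.spectral import (
    band_msc,
    band_power,
    freeze_index,
    freeze_ratio,
    psd_estimate,
    spectral_moments,
)

FS = 500.0


def _tone(freq, duration_s=3.0, fs=FS, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestPSD:
    def test_single_tone_peak(self):
        spec = psd_estimate(_tone(5.0))
        assert abs(spec.frequencies[np.argmax(spec.power)] - 5.0) <= spec.df

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(3)
        sigma = 1.7
        x = sigma * rng.standard_normal(int(60 * FS))
        spec = psd_estimate(x)
        integrated = np.trapezoid(spec.power, spec.frequencies)
        assert abs(integrated - sigma**2) / sigma**2 < 0.10

    def test_equal_tones_equal_band_power(self):
        # default 1-Hz resolution, tones clear of the detrended DC bin
        x = _tone(2.0, 30.0) + _tone(6.0, 30.0)
        spec = psd_estimate(x)
        p2 = band_power(spec, 1.0, 3.0)
        p6 = band_power(spec, 5.0, 7.0)
        assert abs(p2 - p6) / max(p2, p6) < 0.05
        # finer 0.25-Hz resolution resolves a 1-Hz tone exactly as well
        y = _tone(1.0, 30.0) + _tone(5.0, 30.0)
        spec4 = psd_estimate(y, segment_s=4.0)
        p1 = band_power(spec4, 0.5, 2.0)
        p5 = band_power(spec4, 4.0, 6.0)
        assert abs(p1 - p5) / max(p1, p5) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            psd_estimate(np.zeros(100))


class TestBandPower:
    def test_tone_in_freeze_band(self):
        spec = psd_estimate(_tone(5.0, 10.0))
        assert band_power(spec, 3, 8) / band_power(spec, 0.5, 3) > 100

    def test_tone_in_locomotion_band(self):
        spec = psd_estimate(_tone(1.0, 10.0))
        assert band_power(spec, 0.5, 3) / band_power(spec, 0.5, 16) >= 0.9

    def test_zero_signal(self):
        spec = psd_estimate(np.zeros(1500))
        assert band_power(spec, 0.5, 3) == 0.0

    def test_inverted_band_rejected(self):
        spec = psd_estimate(_tone(5.0))
        with pytest.raises(ValueError):
            band_power(spec, 8.0, 3.0)


class TestFreezeIndexRatio:
    def test_equal_power_tones(self):
        # 0.25-Hz resolution so the 1-Hz tone is fully resolved inside
        # the locomotion band
        spec = psd_estimate(_tone(1.0, 30.0) + _tone(5.0, 30.0), segment_s=4.0)
        assert abs(freeze_index(spec) - 1.0) < 0.1
        assert abs(freeze_ratio(spec) - 0.5) < 0.05

    def test_pure_locomotion_tone(self):
        spec = psd_estimate(_tone(1.0, 10.0))
        assert freeze_index(spec) < 0.05

    def test_pure_freeze_tone(self):
        spec = psd_estimate(_tone(5.0, 10.0))
        assert freeze_ratio(spec) > 0.95
        assert freeze_index(spec) > 20


class TestSpectralMoments:
    def test_single_tone_concentrated(self):
        spec = psd_estimate(_tone(5.0, 10.0))
        m = spectral_moments(spec)
        assert abs(m["dominant_frequency"] - 5.0) <= spec.df
        assert abs(m["median_frequency"] - 5.0) <= spec.df
        assert abs(m["mean_frequency"] - 5.0) <= 1.0
        assert m["entropy_psd"] < 0.35

    def test_white_noise_entropy_near_one(self):
        x = np.random.default_rng(0).standard_normal(int(60 * FS))
        assert spectral_moments(psd_estimate(x))["entropy_psd"] > 0.97

    def test_two_tone_mean(self):
        spec = psd_estimate(_tone(2.0, 30.0) + _tone(6.0, 30.0))
        assert abs(spectral_moments(spec)["mean_frequency"] - 4.0) < 0.3

    def test_all_zero_spectrum_rejected(self):
        spec = psd_estimate(np.zeros(1500))
        with pytest.raises(ValueError):
            spectral_moments(spec)


class TestTimeFeatures:
    def test_unit_sine_closed_form(self):
        W = _tone(1.0)[np.newaxis, :]
        stats = _time_stats(W, FS)
        assert stats["n_zero_crossings"][0] == 6
        assert abs(stats["rms"][0] - 1 / np.sqrt(2)) < 0.01
        from fogdetect.features import _peak_stats

        assert _peak_stats(W, FS)["n_peaks"][0] == 3

    def test_constant_zero(self):
        stats = _time_stats(np.zeros((1, 1500)), FS)
        assert stats["rms"][0] == 0
        assert stats["range"][0] == 0
        assert stats["n_zero_crossings"][0] == 0

    def test_identical_axes_fully_correlated(self):
        from fogdetect.features import _rowwise_corr

        W = np.random.default_rng(1).standard_normal((4, 1500))
        np.testing.assert_allclose(_rowwise_corr(W, W), 1.0)


class TestMSC:
    def test_identical_channels_coherence_one(self):
        x = np.random.default_rng(2).standard_normal(1500)
        _, bands = band_msc(np.vstack([x, x]), fs=FS)
        for vals in bands.values():
            np.testing.assert_allclose(vals, 1.0, atol=1e-9)

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(5)
        means = []
        for _ in range(20):
            X = rng.standard_normal((2, 1500))
            _, bands = band_msc(X, fs=FS)
            means.append(np.mean([v[0] for v in bands.values()]))
        assert np.mean(means) < 0.3


class TestBatteryCounts:
    def test_per_sensor_totals(self, small_processed):
        _, _, _, matrix = small_processed
        for sensor, expected in EXPECTED_COUNTS.items():
            assert len(matrix.sensor_columns(sensor)) == expected
        assert matrix.data.shape[1] == sum(EXPECTED_COUNTS.values())

    def test_no_nonfinite_values(self, small_processed):
        _, _, _, matrix = small_processed
        assert np.isfinite(matrix.data.to_numpy()).all()

    def test_feature_dictionary_complete(self, small_processed):
        _, _, _, matrix = small_processed
        fdic = matrix.feature_dictionary()
        assert set(fdic.columns) >= {"name", "sensor", "channel", "domain"}
        assert len(fdic) == matrix.data.shape[1]
        assert fdic["name"].is_unique

    def test_single_window_extraction(self, small_processed):
        proc, anns, windows, _ = small_processed
        from fogdetect.types import WindowSet

        one = WindowSet(windows.windows[:1])
        m = extract_features(proc, one)
        assert m.data.shape == (1, sum(EXPECTED_COUNTS.values()))

    def test_unknown_sensor_group_rejected(self, small_processed):
        proc, _, windows, _ = small_processed
        with pytest.raises(ValueError):
            extract_features(proc, windows, sensors=("thorax",))


def test_sc_tonic_slope_is_line_fit():
    """A linear tonic ramp of slope k yields a slope feature equal to k."""
    from fogdetect.features import extract_sc
    from fogdetect.types import ModalityData, Recording, Window, WindowSet

    fs = 500.0
    k = 0.02
    t = np.arange(int(6 * fs)) / fs
    rng = np.random.default_rng(0)
    phasic = 0.01 * rng.standard_normal(t.size)
    tonic = 2.0 + k * t
    rec = Recording(
        "S01", "T1",
        {"sc": ModalityData(["sc_filtered", "scr", "scl"], fs,
                            np.vstack([phasic + tonic, phasic, tonic]))},
    )
    ws = WindowSet([Window("S01", "T1", 0.0, 3.0, 0)])
    cols: dict = {}
    reg: list = []
    extract_sc(rec, ws, cols, reg)
    assert abs(cols["sc|tonic|slope"][0] - k) < 1e-9
    assert cols["sc|phasic|n_local_min"][0] >= 0


class TestRangeNormalization:
    def test_closed_form(self):
        df = pd.DataFrame({"f": [2.0, 4.0, 6.0]})
        out = RangeNormalizer().fit_transform(df)
        np.testing.assert_allclose(out["f"], [0.0, 0.5, 1.0])

    def test_heldout_clipped(self):
        norm = RangeNormalizer().fit(pd.DataFrame({"f": [0.0, 10.0]}))
        out = norm.transform(pd.DataFrame({"f": [-5.0, 15.0, np.inf]}))
        np.testing.assert_allclose(out["f"], [0.0, 1.0, 1.0])

    def test_idempotent(self):
        df = pd.DataFrame({"f": np.linspace(0, 1, 11)})
        out = RangeNormalizer().fit_transform(df)
        np.testing.assert_allclose(out["f"], df["f"])

    def test_constant_column_dropped(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.warns(UserWarning):
            out = RangeNormalizer().fit_transform(df)
        assert list(out.columns) == ["good"]


def test_direction_of_key_features(small_processed):
    """Across windows with both regimes, the freeze ratio correlates
    positively and the locomotion band power negatively with the FOG label."""
    _, _, windows, matrix = small_processed
    labels = windows.labels
    assert labels.sum() >= 10 and (1 - labels).sum() >= 10
    r, _ = pointbiserial(
        matrix.data[["tibia_acc|x|freeze_ratio",
                     "tibia_acc|x|locomotion_band_power"]], labels
    )
    assert r["tibia_acc|x|freeze_ratio"] > 0.3
    assert r["tibia_acc|x|locomotion_band_power"] < -0.3


def test_column_values_independent_of_channel_order(small_processed):
    """Permuting channel order changes no feature value (named columns)."""
    proc, anns, windows, matrix = small_processed
    from fogdetect.types import ModalityData, Recording

    mod = proc.modalities["tibia_acc"]
    perm = [2, 0, 1]
    shuffled = Recording(
        proc.subject_id, proc.task_id,
        {
            **proc.modalities,
            "tibia_acc": ModalityData(
                [mod.channel_names[i] for i in perm], mod.fs, mod.samples[perm]
            ),
        },
    )
    m2 = extract_features(shuffled, windows, sensors=("tibia",))
    for col in m2.data.columns:
        np.testing.assert_allclose(m2.data[col], matrix.data[col], atol=1e-12)
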