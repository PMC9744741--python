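"""Filtering, resampling, bad-channel detection, interpolation, re-referencing."""

import numpy as np
import pytest
from scipy import signal as sps

from neurogaze.montage import make_montage
from neurogaze.preprocess import (Recording, FilterSpec, BadChannelThresholds,
                                  filter_zerophase, resample,
                                  detect_bad_channels, channel_metrics,
                                  interpolate_bad, rereference_average,
                                  spline_interpolation_matrix)

from conftest import tone

ALPHA_BP = FilterSpec("bandpass", (7.5, 12.0), transition_bw=2.0, order=66)


def _rec(data, fs=250.0, impedances=None):
    data = np.atleast_2d(data)
    return Recording(data=data, fs=fs,
                     labels=tuple(f"E{i+1}" for i in range(data.shape[0])),
                     impedances=impedances)


class TestFilterZerophase:
    def test_passband_identity(self):
        # an order-66 band-pass is shallow; use a sharper design for the gain check
        spec = FilterSpec("bandpass", (7.5, 12.0), transition_bw=2.0, order=300)
        x = tone(10.0, 250.0, 20.0)
        out = filter_zerophase(_rec(x), spec).data[0]
        mid = slice(1000, -1000)
        assert abs(np.abs(out[mid]).max() - 1.0) < 0.05

    def test_stopband_rejection(self):
        x = tone(40.0, 250.0, 20.0)
        out = filter_zerophase(_rec(x), ALPHA_BP).data[0]
        assert np.abs(out[1000:-1000]).max() < 0.01

    def test_impulse_response_symmetric(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        out = filter_zerophase(_rec(x), ALPHA_BP).data[0]
        np.testing.assert_allclose(out[1000 - 200: 1000],
                                   out[1000 + 200: 1000: -1], atol=1e-10)

    def test_output_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(777)
        assert filter_zerophase(_rec(x), ALPHA_BP).n_samples == 777

    def test_cutoff_beyond_nyquist_rejected(self):
        spec = FilterSpec("lowpass", (200.0,), transition_bw=2.0, order=100)
        with pytest.raises(ValueError):
            filter_zerophase(_rec(np.zeros(500)), spec)


class TestResample:
    def test_bookkeeping(self):
        x = np.zeros((3, 5000))
        out = resample(_rec(x, fs=500.0), 250.0)
        assert out.fs == 250.0 and out.n_samples == 2500

    def test_tone_amplitude_preserved(self):
        x = tone(5.0, 500.0, 10.0)
        out = resample(_rec(x, fs=500.0), 250.0).data[0]
        assert abs(np.abs(out[100:-100]).max() - 1.0) < 0.02

    def test_low_frequency_spectrum_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50000)
        rec = _rec(x, fs=500.0)
        out = resample(rec, 250.0)
        f1, p1 = sps.welch(rec.data[0], fs=500.0, nperseg=1000)
        f2, p2 = sps.welch(out.data[0], fs=250.0, nperseg=500)
        m1 = (f1 > 1) & (f1 < 100)
        m2 = (f2 > 1) & (f2 < 100)
        ratio = np.interp(f2[m2], f1[m1], p1[m1]) / p2[m2]
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            resample(_rec(np.zeros(100)), -1.0)


def _clean_multichannel(montage, seed=0, n=5000, fs=250.0):
    """Highly correlated clean channels: one source + small channel noise."""
    rng = np.random.default_rng(seed)
    src = rng.standard_normal(n)
    data = src[None, :] + 0.1 * rng.standard_normal((montage.n_channels, n))
    return Recording(data=data, fs=fs, labels=montage.labels,
                     impedances=np.full(montage.n_channels, 10.0))


class TestDetectBadChannels:
    def test_high_impedance_flagged(self, montage64):
        rec = _clean_multichannel(montage64)
        imp = np.asarray(rec.impedances).copy()
        imp[5] = 120.0
        rec = Recording(data=rec.data, fs=rec.fs, labels=rec.labels,
                        impedances=imp)
        bad = detect_bad_channels(rec, montage64)
        assert montage64.labels[5] in bad

    @pytest.mark.parametrize("seed", range(50))
    def test_no_false_positives_on_clean_data(self, montage64, seed):
        rec = _clean_multichannel(montage64, seed=seed, n=2000)
        assert detect_bad_channels(rec, montage64) == set()

    def test_spiky_channel_flagged_by_two_minor_criteria(self, montage64):
        rec = _clean_multichannel(montage64, seed=1)
        data = rec.data.copy()
        spikes = np.zeros(rec.n_samples)
        rng = np.random.default_rng(2)
        spikes[rng.choice(rec.n_samples, 25, replace=False)] = 60.0
        data[7] = spikes
        rec = Recording(data=data, fs=rec.fs, labels=rec.labels,
                        impedances=rec.impedances)
        bad, metrics = detect_bad_channels(rec, montage64, return_metrics=True)
        th = BadChannelThresholds()
        assert metrics["kurtosis_z"][7] > th.kurtosis_z
        assert metrics["improbability_z"][7] > th.improbability_z
        assert montage64.labels[7] in bad

    def test_too_few_channels_rejected(self):
        m = make_montage(4)
        rec = Recording(data=np.zeros((2, 100)), fs=250.0, labels=("A", "B"),
                        impedances=np.zeros(2))
        with pytest.raises(ValueError):
            channel_metrics(rec, m)


class TestInterpolateBad:
    def test_no_bad_channels_is_identity(self, montage64):
        rec = _clean_multichannel(montage64)
        out = interpolate_bad(rec, set(), montage64)
        assert np.array_equal(out.data, rec.data)

    def test_constant_field_reproduced(self, montage64):
        s = tone(3.0, 250.0, 4.0)
        data = np.tile(s, (montage64.n_channels, 1))
        rec = Recording(data=data, fs=250.0, labels=montage64.labels)
        out = interpolate_bad(rec, {montage64.labels[10]}, montage64)
        err = np.abs(out.data[10] - s).max() / np.abs(s).max()
        assert err < 0.01

    def test_dipolar_topography_reconstruction(self, montage64):
        # smooth dipolar field sampled at the electrodes; hold one out
        dipole = np.array([0.0, -0.6, 0.55])
        gain = montage64.positions @ dipole
        s = tone(8.0, 250.0, 2.0)
        data = np.outer(gain, s)
        rec = Recording(data=data, fs=250.0, labels=montage64.labels)
        idx = 20
        out = interpolate_bad(rec, {montage64.labels[idx]}, montage64)
        rmse = np.sqrt(np.mean((out.data[idx] - data[idx]) ** 2))
        true_rms = np.sqrt(np.mean(data[idx] ** 2))
        assert rmse < 0.1 * true_rms

    def test_all_bad_rejected(self, montage64):
        rec = _clean_multichannel(montage64)
        with pytest.raises(ValueError):
            interpolate_bad(rec, set(montage64.labels), montage64)

    def test_warning_when_many_bad(self, montage64, caplog):
        rec = _clean_multichannel(montage64)
        bad = set(montage64.labels[:20])
        with caplog.at_level("WARNING"):
            interpolate_bad(rec, bad, montage64)
        assert any("25%" in m for m in caplog.messages)

    def test_interpolation_matrix_rows_sum_to_one_for_constants(self, montage64):
        good = montage64.positions[:50]
        bad = montage64.positions[50:]
        t = spline_interpolation_matrix(good, bad)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-3)


class TestRereferenceAverage:
    def test_column_means_zero(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((8, 1000)))
        out = rereference_average(rec)
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal((8, 1000)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_bipolar_differences_unchanged(self):
        rng = np.random.default_rng(2)
        rec = _rec(rng.standard_normal((8, 1000)))
        out = rereference_average(rec)
        np.testing.assert_allclose(rec.data[3] - rec.data[5],
                                   out.data[3] - out.data[5], atol=1e-12)


def test_filter_and_rereference_commute():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((6, 4000))
    data -= data.mean(axis=1, keepdims=True)
    rec = _rec(data)
    a = rereference_average(filter_zerophase(rec, ALPHA_BP))
    b = filter_zerophase(rereference_average(rec), ALPHA_BP)
    np.testing.assert_allclose(a.data, b.data, atol=1e-10)
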