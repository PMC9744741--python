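"""Amplitude envelopes, DFA, fixation extraction, behavioural LRTC exponents."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sstats

from neurogaze.preprocess import Recording
from neurogaze.synth import (CohortSpec, GazeRecording, make_cohort, synth_fgn,
                             synth_eeg, synth_gaze)
from neurogaze.dynamics import (amplitude_envelope, dfa,
                                envelope_dfa_exponents, extract_fixations,
                                behavioural_dfa, DFAParams, FixationSeries,
                                ALPHA_BAND)

from conftest import tone
from oracle_dfa import reference_dfa


def _rec(data, fs=250.0):
    data = np.atleast_2d(data)
    return Recording(data=data, fs=fs,
                     labels=tuple(f"E{i+1}" for i in range(data.shape[0])))


class TestAmplitudeEnvelope:
    def test_constant_tone_envelope(self):
        x = tone(10.0, 250.0, 20.0, amplitude=2.5)
        env = amplitude_envelope(_rec(x), ALPHA_BAND, order=66)
        mid = env.values[0, 500:-500]
        assert np.abs(mid - 2.5).max() / 2.5 < 0.03

    def test_slow_modulator_recovered(self):
        fs = 250.0
        t = np.arange(int(40 * fs)) / fs
        modulator = 1.0 + 0.5 * np.cos(2 * np.pi * 0.2 * t)
        x = modulator * np.sin(2 * np.pi * 10.0 * t)
        env = amplitude_envelope(_rec(x), ALPHA_BAND, order=66)
        mid = slice(500, -500)
        r = np.corrcoef(env.values[0, mid], modulator[mid])[0, 1]
        assert r > 0.98

    def test_fgn_modulation_recovered(self):
        # an fGn-modulated alpha carrier: the extracted envelope tracks the
        # modulating fGn (built from the generator's own primitives)
        from neurogaze.synth import _narrowband_const_env, _envelope_from_fgn, _rng
        fs, n = 250.0, 30000
        rng = _rng(42)
        carrier = _narrowband_const_env(n, 10.0, fs, rng)
        modulator = _envelope_from_fgn(n, 0.8, rng)
        x = modulator * carrier + 0.1 * rng.standard_normal(n)
        env = amplitude_envelope(_rec(x), ALPHA_BAND, order=66)

        def halfsec_blocks(v, k=125):
            v = v[500:-500]
            return v[: len(v) // k * k].reshape(-1, k).mean(axis=1)

        # the modulator is broadband fGn; the envelope can only carry its
        # sub-band (slow) structure, so compare at envelope bandwidth
        r = sstats.spearmanr(halfsec_blocks(env.values[0]),
                             halfsec_blocks(modulator))[0]
        assert r > 0.8

    def test_order_too_large_rejected(self):
        with pytest.raises(ValueError):
            amplitude_envelope(_rec(np.zeros(50)), ALPHA_BAND, order=66)


class TestDFA:
    def test_white_noise_exponent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2 ** 14)
        res = dfa(x, scale_lo=16, scale_hi=4096, n_scales=15)
        assert abs(res.exponent - 0.5) < 0.05

    @pytest.mark.parametrize("hurst", [0.6, 0.8])
    def test_fgn_exponent_matches_hurst_and_oracle(self, hurst):
        x = synth_fgn(2 ** 14, hurst, seed=4)
        res = dfa(x, scale_lo=16, scale_hi=4096, n_scales=15)
        _, _, oracle = reference_dfa(x, 16, 4096, n_scales=15)
        assert abs(res.exponent - hurst) < 0.05
        assert abs(res.exponent - oracle) < 0.02

    def test_shuffling_destroys_memory(self):
        x = synth_fgn(2 ** 14, 0.85, seed=5)
        rng = np.random.default_rng(5)
        res = dfa(rng.permutation(x), scale_lo=16, scale_hi=4096)
        assert abs(res.exponent - 0.5) < 0.05

    def test_affine_invariance(self):
        x = synth_fgn(4096, 0.7, seed=6)
        a = dfa(x, scale_lo=8, scale_hi=1024).exponent
        b = dfa(5.0 * x + 100.0, scale_lo=8, scale_hi=1024).exponent
        assert a == pytest.approx(b, abs=1e-9)

    def test_fluctuations_nondecreasing(self):
        for seed, hurst in ((0, 0.5), (1, 0.7), (2, 0.9)):
            x = synth_fgn(2 ** 13, hurst, seed=seed)
            res = dfa(x, scale_lo=16, scale_hi=2048)
            assert np.all(np.diff(res.fluctuations) > 0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            dfa(np.ones(4096), scale_lo=8, scale_hi=512)

    def test_scale_too_large_rejected(self):
        with pytest.raises(ValueError):
            dfa(np.random.default_rng(0).standard_normal(1000),
                scale_lo=400, scale_hi=500)

    def test_batched_rows_match_single(self):
        xs = np.stack([synth_fgn(4096, h, seed=7) for h in (0.6, 0.8)])
        batch = dfa(xs, scale_lo=8, scale_hi=1024)
        singles = [dfa(x, scale_lo=8, scale_hi=1024).exponent for x in xs]
        np.testing.assert_allclose(batch.exponent, singles, atol=1e-12)


class TestExtractFixations:
    def test_subthreshold_trace_is_one_fixation(self):
        gaze = GazeRecording(velocity=np.full(5000, 5.0),
                             true_state=np.zeros(5000, dtype=np.int8),
                             fs_gaze=500.0)
        fix = extract_fixations(gaze, velocity_threshold=30.0)
        assert fix.n_fixations == 1
        assert not fix.states.any()

    def test_three_saccade_bursts_give_four_fixations(self):
        fs = 500.0
        v = np.full(int(4 * fs), 5.0)
        for start_s in (1.0, 2.0, 3.0):
            i = int(start_s * fs)
            v[i:i + 20] = 200.0
        gaze = GazeRecording(velocity=v, true_state=(v > 30).astype(np.int8),
                             fs_gaze=fs)
        fix = extract_fixations(gaze, velocity_threshold=30.0)
        assert fix.n_fixations == 4

    def test_agreement_with_ground_truth(self):
        cohort = make_cohort(CohortSpec(seed=9, n_static=4, n_dynamic=4))
        for sub in cohort:
            gaze = synth_gaze(sub, duration_s=120.0, fs_gaze=500.0, seed=9)
            fix = extract_fixations(gaze)
            agreement = np.mean(fix.states == gaze.true_state)
            assert agreement >= 0.95

    def test_empty_trace_rejected(self):
        gaze = GazeRecording(velocity=np.array([]), true_state=np.array([]),
                             fs_gaze=500.0)
        with pytest.raises(ValueError):
            extract_fixations(gaze)


class TestBehaviouralDFA:
    def test_iid_binary_noise_is_white(self):
        rng = np.random.default_rng(10)
        states = rng.integers(0, 2, 2 ** 14).astype(np.int8)
        fix = FixationSeries(states=states, fs=500.0, n_fixations=100)
        res = behavioural_dfa(fix, DFAParams(scale_lo_s=0.032, scale_hi_s=2.0))
        assert abs(res.exponent - 0.5) < 0.05

    def test_exponent_monotone_in_hurst(self):
        # rank order of mean exponents preserved across generator settings
        base = make_cohort(CohortSpec(seed=0))[0]
        means = []
        for hurst in (0.59, 0.72, 0.85):
            sub = dataclasses.replace(base, hurst_fix=hurst)
            exps = []
            for seed in range(10):
                gaze = synth_gaze(sub, duration_s=600.0, fs_gaze=500.0, seed=seed)
                exps.append(behavioural_dfa(extract_fixations(gaze)).exponent)
            means.append(np.mean(exps))
        assert means[0] < means[1] < means[2]

    def test_few_fixations_warns(self, caplog):
        states = np.array([0] * 500 + [1] * 20 + [0] * 500, dtype=np.int8)
        fix = FixationSeries(states=states, fs=250.0, n_fixations=2)
        with caplog.at_level("WARNING"):
            behavioural_dfa(fix, DFAParams(scale_lo_s=0.05, scale_hi_s=1.0))
        assert any("unstable" in m for m in caplog.messages)


def test_envelope_exponent_recovers_hurst_ranking(montage64):
    """Per-subject alpha-envelope DFA exponents track the generative Hurst
    exponents across the default cohort (Spearman r > 0.7)."""
    spec = CohortSpec(seed=13)
    cohort = make_cohort(spec)
    truth = [s.hurst_alpha for s in cohort]
    est = []
    scalp = montage64.scalp_mask
    for sub in cohort:
        rec = synth_eeg(sub, montage64, "eyes_open", duration_s=spec.duration_s,
                        fs=spec.fs_eeg, seed=13)
        est.append(envelope_dfa_exponents(rec)[scalp].mean())
    r = sstats.spearmanr(truth, est)[0]
    assert r > 0.7


def test_brain_behaviour_lrtc_link_across_studies(study_results):
    """Eyes-open alpha-envelope exponents correlate positively (and nominally
    significantly) with behavioural exponents in at least 80% of 20 runs."""
    hits = sum(res["dfa"]["brain_vs_behaviour"]["eyes_open"]["r"] > 0
               and res["dfa"]["brain_vs_behaviour"]["eyes_open"]["p"] < 0.05
               for res in study_results)
    assert hits >= 16
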