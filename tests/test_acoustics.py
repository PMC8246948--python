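"""Acoustic extraction oracles: envelope of known tones, F0 of known
harmonics, segmentation arithmetic, and end-to-end recovery on rendered
synthetic speech."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

from gesturespeech import acoustics as ac
from gesturespeech.io_session import AudioTrack

from conftest import constant_tracks


def _tone(freq=440.0, amp=0.5, duration=1.0, fs=44100.0):
    t = np.arange(int(duration * fs)) / fs
    return AudioTrack(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)


def _harmonic(f0=200.0, duration=1.0, fs=44100.0, nharm=6):
    t = np.arange(int(duration * fs)) / fs
    x = sum(np.sin(2 * np.pi * k * f0 * t) / k for k in range(1, nharm + 1))
    return AudioTrack(samples=0.3 * x / np.abs(x).max(), fs=fs)


class TestEnvelope:
    def test_constant_tone_recovers_amplitude(self):
        env = ac.compute_envelope(_tone(amp=0.5))
        interior = env.env[60:-60]  # clear of smoothing edge effects
        assert np.all(np.abs(interior - 0.5) / 0.5 < 0.02)

    def test_silence_gives_zero_envelope(self):
        env = ac.compute_envelope(AudioTrack(samples=np.zeros(44100)))
        assert np.allclose(env.env, 0.0)

    def test_am_modulator_recovered(self):
        fs = 44100.0
        t = np.arange(int(4 * fs)) / fs
        modulator = 0.5 * (1 - np.cos(2 * np.pi * 2.0 * t))  # 2-Hz raised cosine
        audio = AudioTrack(samples=modulator * np.sin(2 * np.pi * 440 * t), fs=fs)
        env = ac.compute_envelope(audio)
        mod240 = 0.5 * (1 - np.cos(2 * np.pi * 2.0 * env.t))
        n = len(env.env)
        sl = slice(240, n - 240)
        r = np.corrcoef(env.env[sl], mod240[sl])[0, 1]
        assert r > 0.99

    @pytest.mark.parametrize("a", [0.25, 3.0])
    def test_homogeneity(self, a):
        audio = _harmonic()
        base = ac.compute_envelope(audio)
        scaled = ac.compute_envelope(
            AudioTrack(samples=a * audio.samples, fs=audio.fs))
        assert np.allclose(scaled.env, a * base.env, rtol=1e-6, atol=1e-9)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            ac.compute_envelope(AudioTrack(samples=np.empty(0)))


class TestF0Tracking:
    def test_harmonic_tone_tracked_within_two_hz(self):
        f0 = ac.track_f0(_harmonic(200.0), "female")
        voiced = f0.f0[np.isfinite(f0.f0)]
        assert len(voiced) > 0.8 * len(f0.f0)
        assert abs(np.median(voiced) - 200.0) < 2.0

    def test_white_noise_yields_no_voiced_frames(self):
        rng = np.random.default_rng(0)
        audio = AudioTrack(samples=0.01 * rng.normal(size=44100))
        f0 = ac.track_f0(audio, "female")
        assert np.isfinite(f0.f0).sum() == 0

    def test_below_range_tone_yields_no_voiced_frames(self):
        f0 = ac.track_f0(_harmonic(60.0), "female")  # floor is 80 Hz
        assert np.isfinite(f0.f0).sum() == 0

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            ac.track_f0(_tone(), "other")


class TestSegmentation:
    def _tracks_from_mask(self, mask, env_values=None, fs=240.0):
        n = len(mask)
        t = np.arange(n) / fs
        f0 = ac.F0Track(t=t, f0=np.where(mask, 200.0, np.nan), fs=fs)
        env_arr = env_values if env_values is not None else np.ones(n)
        env = ac.EnvelopeTrack(t=t, env=env_arr, fs=fs)
        return f0, env

    def test_two_runs_and_interval(self):
        n = 240
        mask = np.zeros(n, dtype=bool)
        mask[0:48] = True      # [0.0, 0.2) s
        mask[120:192] = True   # [0.5, 0.8) s
        env_vals = np.ones(n)
        env_vals[24] = 5.0     # peak at 0.10 s
        env_vals[144] = 5.0    # peak at 0.60 s
        f0, env = self._tracks_from_mask(mask, env_vals)
        events = ac.segment_vocalizations(f0, env)
        assert len(events) == 2
        assert events[0].duration_ms == pytest.approx(200.0)
        assert events[1].duration_ms == pytest.approx(300.0)
        interval_ms = (events[1].peak_env_time - events[0].peak_env_time) * 1000
        assert interval_ms == pytest.approx(500.0)

    def test_single_frame_event(self):
        mask = np.zeros(240, dtype=bool)
        mask[100] = True
        f0, env = self._tracks_from_mask(mask)
        events = ac.segment_vocalizations(f0, env)
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(1000.0 / 240.0)

    def test_gap_merging(self):
        mask = np.zeros(240, dtype=bool)
        mask[0:48] = True
        mask[49:97] = True  # 1-frame gap (~4.2 ms)
        f0, env = self._tracks_from_mask(mask)
        assert len(ac.segment_vocalizations(f0, env, min_gap_ms=0.0)) == 2
        assert len(ac.segment_vocalizations(f0, env, min_gap_ms=10.0)) == 1

    def test_empty_track_gives_empty_list(self):
        f0, env = self._tracks_from_mask(np.zeros(240, dtype=bool))
        assert ac.segment_vocalizations(f0, env) == []

    @given(st_hyp.lists(st_hyp.booleans(), min_size=1, max_size=400))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_events_partition_voiced_frames(self, mask_list):
        mask = np.array(mask_list, dtype=bool)
        f0, env = self._tracks_from_mask(mask)
        events = ac.segment_vocalizations(f0, env)
        fs = 240.0
        covered = np.zeros(len(mask), dtype=bool)
        prev_offset = -np.inf
        for ev in events:
            assert ev.onset >= prev_offset  # ordered, disjoint
            prev_offset = ev.offset
            i0 = int(round(ev.onset * fs))
            i1 = int(round(ev.offset * fs))
            assert not covered[i0:i1].any()
            covered[i0:i1] = True
        assert np.array_equal(covered, mask)


class TestTrialSummary:
    def test_rate_unit_conversion(self):
        env, f0 = constant_tracks(duration_s=2.0)
        # two 200-ms runs
        mask = np.zeros(480, dtype=bool)
        mask[0:48] = True
        mask[240:288] = True
        f0.f0 = np.where(mask, 200.0, np.nan)
        events = ac.segment_vocalizations(f0, env)
        summ = ac.trial_acoustic_summary(events, f0, env, (0.5, 0.2))
        assert summ.voc_duration_hz == pytest.approx(5.0)
        assert summ.n_events == 2

    def test_degenerate_envelope_sd_flagged(self):
        env, f0 = constant_tracks(duration_s=1.0)
        events = ac.segment_vocalizations(f0, env)
        with pytest.raises(ValueError):
            ac.trial_acoustic_summary(events, f0, env, (1.0, 0.0))

    def test_no_events_gives_missing_rates(self):
        env, f0 = constant_tracks(duration_s=1.0)
        f0.f0 = np.full_like(f0.f0, np.nan)
        summ = ac.trial_acoustic_summary([], f0, env, (0.5, 0.2))
        assert summ.n_events == 0
        assert np.isnan(summ.voc_duration_hz) and np.isnan(summ.mean_f0)


class TestEndToEndRecovery:
    def test_f0_and_envelope_recovered_from_rendered_audio(self, rendered_trial):
        truth, audio = rendered_trial
        env = ac.compute_envelope(audio)
        f0 = ac.track_f0(audio, "female")
        n = min(len(env.env), len(truth.true_env), len(f0.f0))
        both = np.isfinite(truth.true_f0[:n]) & np.isfinite(f0.f0[:n])
        rmse = np.sqrt(np.mean((f0.f0[:n][both] - truth.true_f0[:n][both]) ** 2))
        assert rmse < 3.0
        r = np.corrcoef(env.env[:n], truth.true_env[:n])[0, 1]
        assert r > 0.95

    def test_constant_f0_round_trip(self):
        from gesturespeech import synthetic as syn
        n = int(5.0 * 240)
        truth = syn.GroundTruth(condition="passive", duration_s=5.0)
        truth.true_env = np.full(n, 0.5)
        truth.true_f0 = np.full(n, 200.0)
        audio = syn.render_audio(truth, rng_seed=0)
        f0 = ac.track_f0(audio, "female")
        voiced = f0.f0[np.isfinite(f0.f0)]
        assert abs(np.median(voiced) - 200.0) < 2.0

    def test_all_pause_trial_yields_no_events(self):
        from gesturespeech import synthetic as syn
        n = int(5.0 * 240)
        truth = syn.GroundTruth(condition="passive", duration_s=5.0)
        truth.true_env = np.zeros(n)
        truth.true_f0 = np.full(n, np.nan)
        audio = syn.render_audio(truth, rng_seed=2)
        f0 = ac.track_f0(audio, "female")
        env = ac.compute_envelope(audio)
        m = min(len(f0.f0), len(env.env))
        f0 = ac.F0Track(t=f0.t[:m], f0=f0.f0[:m])
        env = ac.EnvelopeTrack(t=env.t[:m], env=env.env[:m])
        assert ac.segment_vocalizations(f0, env) == []
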