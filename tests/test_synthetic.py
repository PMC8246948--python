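"""Generator ground truth: kinematic closed forms, coupling bookkeeping,
determinism, and the invariants every generated trial must satisfy."""

import numpy as np
import pytest

from gesturespeech import alignment, synthetic as syn
from gesturespeech.acoustics import segment_vocalizations


def _numeric_accel(z, fs=240.0):
    dt = 1.0 / fs
    return np.gradient(np.gradient(z, dt), dt)


class TestKinematicsGeneration:
    def test_sharpness_one_is_pure_sinusoid(self):
        kp = syn.KinematicsParams(freq_mean=1.33, freq_sd=0.0,
                                  amplitude_cm=10.0, beat_sharpness=1.0,
                                  sensor_noise_sd_cm=0.0)
        motion, _ = syn.generate_kinematics(kp, 60.0, rng_seed=0)
        a = _numeric_accel(motion.z)
        expected = 10.0 * (2 * np.pi * 1.33) ** 2
        assert abs(np.abs(a[200:-200]).max() - expected) / expected < 0.02

    def test_beat_count_matches_tempo(self):
        kp = syn.KinematicsParams(freq_mean=1.33, freq_sd=0.0,
                                  sensor_noise_sd_cm=0.0)
        _, truth = syn.generate_kinematics(kp, 60.0, rng_seed=1)
        assert abs(len(truth.beat_times) - 79.8) <= 1.0

    def test_arm_exceeds_wrist_deceleration(self):
        decels = {}
        for cond, amp in (("arm", 25.0), ("wrist", 10.0)):
            kp = syn.KinematicsParams(freq_mean=1.33, amplitude_cm=amp)
            _, truth = syn.generate_kinematics(kp, 30.0, rng_seed=3)
            decels[cond] = truth.max_decel_values.mean()
        assert decels["arm"] > decels["wrist"]

    def test_sharpness_below_one_rejected(self):
        with pytest.raises(syn.ParameterError):
            syn.KinematicsParams(beat_sharpness=0.5)

    def test_short_duration_rejected(self):
        with pytest.raises(syn.ParameterError):
            syn.generate_kinematics(syn.KinematicsParams(), 2.0, rng_seed=0)


class TestSpeechGeneration:
    def test_bump_gains_equal_mass_times_beta_times_decel(self):
        d = 500.0
        truth = syn.GroundTruth(condition="", duration_s=10.0,
                                beat_times=np.array([2.0, 4.0, 6.0]),
                                decel_onset_times=np.array([1.8, 3.8, 5.8]),
                                max_decel_values=np.full(3, d))
        cp = syn.CouplingParams()
        sp = syn.SpeakerParams.for_sex("female")
        out = syn.generate_speech_tracks(sp, cp, truth, "arm", 10.0, rng_seed=0)
        expected = cp.mass_factor["arm"] * cp.beta_env * d
        assert np.allclose(out.env_bump_gains, expected)
        expected_f0 = cp.mass_factor["arm"] * cp.beta_f0 * d
        assert np.allclose(out.f0_bump_gains, expected_f0)

    def test_passive_with_beats_rejected(self):
        truth = syn.GroundTruth(condition="", duration_s=10.0,
                                beat_times=np.array([2.0]),
                                max_decel_values=np.array([100.0]))
        sp = syn.SpeakerParams.for_sex("male")
        with pytest.raises(syn.ParameterError):
            syn.generate_speech_tracks(sp, syn.CouplingParams(), truth,
                                       "passive", 10.0, rng_seed=0)

    def test_zero_coupling_has_no_beat_locked_structure(self):
        cp0 = syn.CouplingParams(beta_env=0.0, beta_f0=0.0)
        sp = syn.SpeakerParams.for_sex("female")
        epochs = []
        for seed in range(10):
            kp = syn.KinematicsParams.for_condition("wrist")
            _, ktruth = syn.generate_kinematics(kp, 30.0, rng_seed=seed)
            truth = syn.generate_speech_tracks(sp, cp0, ktruth, "wrist", 30.0,
                                               rng_seed=100 + seed)
            epochs.extend(alignment.extract_epochs(
                list(truth.beat_times), truth.env_track(), truth.f0_track()))
        df = alignment.epochs_to_frame(epochs)
        traj = df.groupby("rel_t_ms")["env"].agg(["mean", "sem"])
        dev = np.abs(traj["mean"] - traj["mean"].mean())
        assert (dev < 3.0 * traj["sem"]).all()

    def test_vocalization_rate_near_six_hertz(self):
        sp = syn.SpeakerParams.for_sex("female")  # 160-ms runs, 200-ms pauses
        truth = syn.GroundTruth(condition="passive", duration_s=60.0)
        out = syn.generate_speech_tracks(sp, syn.CouplingParams(), truth,
                                         "passive", 60.0, rng_seed=4)
        events = segment_vocalizations(out.f0_track(), out.env_track())
        rate_hz = 1000.0 / np.mean([e.duration_ms for e in events])
        assert 5.0 <= rate_hz <= 8.0

    def test_envelope_peak_monotone_in_coupling_gain(self):
        peaks = []
        for beta in (0.5e-4, 1.0e-4, 2.0e-4):
            kp = syn.KinematicsParams.for_condition("arm")
            _, ktruth = syn.generate_kinematics(kp, 30.0, rng_seed=9)
            cp = syn.CouplingParams(beta_env=beta)
            sp = syn.SpeakerParams.for_sex("female")
            truth = syn.generate_speech_tracks(sp, cp, ktruth, "arm", 30.0,
                                               rng_seed=11)
            eps = alignment.extract_epochs(list(truth.beat_times),
                                           truth.env_track(), truth.f0_track())
            df = alignment.epochs_to_frame(eps)
            peaks.append(df.groupby("rel_t_ms")["env"].mean().max())
        assert peaks[0] < peaks[1] < peaks[2]


class TestSessions:
    def test_session_arithmetic(self):
        trials = syn.simulate_session(5, 2, master_seed=2,
                                      duration_mean_s=12.0, duration_sd_s=1.0)
        assert len(trials) == 5 * 2 * 3
        conds = [t.condition for t in trials]
        assert conds.count("passive") == conds.count("arm") == 10

    def test_trial_durations_near_mean(self):
        trials = syn.simulate_session(12, 1, master_seed=8)
        durs = [t.truth.duration_s for t in trials]
        assert abs(np.mean(durs) - 26.0) < 2.0

    def test_simulation_deterministic(self):
        a = syn.simulate_session(3, 1, master_seed=7, duration_mean_s=12.0)
        b = syn.simulate_session(3, 1, master_seed=7, duration_mean_s=12.0)
        for ta, tb in zip(a, b):
            assert ta.condition == tb.condition and ta.sex == tb.sex
            assert np.array_equal(ta.truth.true_env, tb.truth.true_env)
            assert np.array_equal(ta.truth.beat_times, tb.truth.beat_times)

    def test_generated_session_files_deterministic(self, tmp_path):
        kw = dict(n_participants=2, trials_per_condition=1, master_seed=3,
                  duration_mean_s=10.0, duration_sd_s=0.5)
        syn.generate_session(tmp_path / "a", **kw)
        syn.generate_session(tmp_path / "b", **kw)
        ma = (tmp_path / "a" / "manifest.csv").read_bytes()
        mb = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert ma == mb
        ta = (tmp_path / "a" / "truth.csv").read_bytes()
        tb = (tmp_path / "b" / "truth.csv").read_bytes()
        assert ta == tb

    @pytest.mark.parametrize("seed", range(25))
    def test_ground_truth_invariants(self, seed):
        cond = ("wrist", "arm")[seed % 2]
        kp = syn.KinematicsParams.for_condition(cond)
        _, ktruth = syn.generate_kinematics(kp, 10.0, rng_seed=seed)
        cp = syn.CouplingParams()
        sp = syn.SpeakerParams.for_sex(("female", "male")[seed % 3 == 0])
        truth = syn.generate_speech_tracks(sp, cp, ktruth, cond, 10.0,
                                           rng_seed=1000 + seed)
        truth.validate()
        assert np.all(np.diff(truth.beat_times) > 0)
        assert np.all(truth.max_decel_values >= 0)
        assert np.allclose(
            truth.env_bump_gains,
            cp.mass_factor[cond] * cp.beta_env * truth.max_decel_values)
        assert all(0 <= a < b <= 10.0 + 1e-9 for a, b in truth.voiced_intervals)
        voiced = np.isfinite(truth.true_f0)
        assert np.all(truth.true_env >= 0)
        if voiced.any():
            assert np.all(truth.true_f0[voiced] > 0)


class TestRenderAudio:
    def test_out_of_range_f0_rejected(self):
        truth = syn.GroundTruth(condition="passive", duration_s=5.0)
        n = int(5.0 * 240)
        truth.true_env = np.ones(n)
        truth.true_f0 = np.full(n, 20.0)  # below the 30-Hz floor
        with pytest.raises(syn.SynthesisError):
            syn.render_audio(truth)

    def test_all_pause_trial_renders_noise_only(self):
        truth = syn.GroundTruth(condition="passive", duration_s=5.0)
        n = int(5.0 * 240)
        truth.true_env = np.zeros(n)
        truth.true_f0 = np.full(n, np.nan)
        audio = syn.render_audio(truth, rng_seed=1)
        assert np.abs(audio.samples).max() < 0.05
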