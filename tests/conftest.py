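import numpy as np
import pytest

from gesturespeech import synthetic as syn
from gesturespeech.acoustics import EnvelopeTrack, F0Track
from gesturespeech.io_session import MotionTrace


@pytest.fixture(scope="session")
def rendered_trial():
    """One 25-s arm trial with default coupling, rendered to audio."""
    kp = syn.KinematicsParams.for_condition("arm")
    motion, truth = syn.generate_kinematics(kp, 25.0, rng_seed=42)
    sp = syn.SpeakerParams.for_sex("female")
    truth = syn.generate_speech_tracks(sp, syn.CouplingParams(), truth, "arm",
                                       25.0, rng_seed=7)
    audio = syn.render_audio(truth, rng_seed=3)
    return truth, audio


@pytest.fixture(scope="session")
def small_session():
    """8 participants x 1 trial/condition with default coupling (in memory)."""
    return syn.simulate_session(8, 1, master_seed=5,
                                duration_mean_s=15.0, duration_sd_s=2.0)


def constant_tracks(duration_s=20.0, env_value=1.0, f0_value=200.0, fs=240.0):
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    env = EnvelopeTrack(t=t, env=np.full(n, env_value), fs=fs)
    f0 = F0Track(t=t, f0=np.full(n, f0_value), fs=fs)
    return env, f0


def sine_motion(amplitude_cm=10.0, freq_hz=1.33, duration_s=60.0, fs=240.0,
                phase=0.0):
    t = np.arange(int(round(duration_s * fs))) / fs
    z = amplitude_cm * np.cos(2 * np.pi * freq_hz * t + phase)
    return MotionTrace(t=t, z=z, fs=fs)
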