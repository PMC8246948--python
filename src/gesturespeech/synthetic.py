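"""Synthetic sessions with known gesture-speech coupling.

The generator emulates the statistical structure the analysis assumes:

* rhythmic vertical limb movement near 1.33 Hz whose downstroke ends in an
  abrupt stop (the *beat*) at the position minimum (maximum extension),
  with larger amplitude -- hence larger deceleration -- for arm than wrist;
* fluent speech as alternating voiced/pause runs with a sex-dependent F0
  baseline and a positive amplitude envelope;
* a transient boost to envelope and F0 centered shortly before each beat,
  whose gain is ``mass_factor(condition) * beta * max_decel`` -- the
  physical-impulse mechanism (impulse = effector mass x change in
  velocity), with arm > wrist > passive = 0.

Every injected quantity is recorded in a :class:`GroundTruth` so that each
downstream stage (event detection, epoching, model fitting) can be scored
against what was put in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import io_session as io
from .acoustics import EnvelopeTrack, F0Track, TRACK_FS
from .io_session import AudioTrack, MotionTrace, SessionManifest, TrialEntry

CONDITIONS = io.CONDITIONS


class ParameterError(ValueError):
    pass


class SynthesisError(ValueError):
    pass


@dataclass
class CouplingParams:
    """Gesture-speech coupling gains and bump geometry.

    beta_env / beta_f0 are boosts per unit deceleration (envelope units and
    Hz per cm/s^2); mass_factor is the effector-mass ratio with
    arm > wrist > 0 and passive = 0.  The bump is a Gaussian of FWHM
    ``bump_width_ms`` centered ``bump_center_offset_ms`` relative to the
    maximum extension (negative = before, during the deceleration phase).
    ``env_offset`` / ``f0_offset_hz`` add condition-level baseline shifts,
    used by the parameter-recovery suites.
    """

    beta_env: float = 1e-4
    beta_f0: float = 1e-3
    mass_factor: Mapping[str, float] = field(
        default_factory=lambda: {"passive": 0.0, "wrist": 0.5, "arm": 1.0})
    bump_center_offset_ms: float = -100.0
    bump_width_ms: float = 120.0
    env_offset: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CONDITIONS})
    f0_offset_hz: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in CONDITIONS})
    #: per-condition override of beta_f0 (None = use beta_f0)
    beta_f0_by_condition: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if self.mass_factor["passive"] != 0.0:
            raise ParameterError("mass_factor(passive) must be 0")
        if not (self.mass_factor["arm"] > self.mass_factor["wrist"] > 0.0):
            raise ParameterError("mass_factor must satisfy arm > wrist > 0")
        if not (-400.0 <= self.bump_center_offset_ms <= 0.0):
            raise ParameterError("bump_center_offset_ms must lie in [-400, 0]")

    def beta_f0_for(self, condition: str) -> float:
        if self.beta_f0_by_condition is not None:
            return self.beta_f0_by_condition.get(condition, self.beta_f0)
        return self.beta_f0


@dataclass
class SpeakerParams:
    """Baseline speech parameters for one speaker."""

    sex: str
    f0_base: float  # Hz
    f0_sd: float = 15.0  # slow-drift SD in Hz
    f0_jitter_sd: float = 2.0
    env_base: float = 1.0  # arbitrary units
    env_sd: float = 0.25
    env_jitter_sd: float = 0.05
    voiced_dur_mean_ms: float = 160.0
    voiced_dur_sd_ms: float = 80.0
    pause_dur_mean_ms: float = 200.0
    pause_dur_sd_ms: float = 120.0
    f0_intercept: float = 0.0  # per-participant random offset
    env_intercept: float = 0.0

    #: sex-dependent F0 baselines; the 73-Hz gap matches typical male/female
    #: fundamental-frequency separation in read speech
    F0_BASE = {"female": 210.0, "male": 137.0}

    def __post_init__(self):
        if self.sex not in io.SEXES:
            raise ParameterError(f"unknown sex {self.sex!r}")
        lo, hi = {"male": (50.0, 400.0), "female": (80.0, 640.0)}[self.sex]
        if not (lo < self.f0_base < hi):
            raise ParameterError("f0_base outside the sex-appropriate tracking range")
        for v in (self.voiced_dur_mean_ms, self.pause_dur_mean_ms):
            if v <= 0:
                raise ParameterError("durations must be positive")

    @classmethod
    def for_sex(cls, sex: str, **kw) -> "SpeakerParams":
        return cls(sex=sex, f0_base=cls.F0_BASE[sex], **kw)


@dataclass
class KinematicsParams:
    """Limb-movement waveform parameters.

    ``amplitude_cm`` is the peak amplitude (position swings +/-A around its
    mean); ``beat_sharpness`` >= 1 is the power-law phase-warp exponent of
    the downstroke -- 1 gives a pure sinusoid, larger values end the
    downstroke in a progressively more abrupt stop (peak deceleration
    scales roughly with its square).
    """

    freq_mean: float = 1.33  # Hz, the 80-BPM target tempo
    freq_sd: float = 0.05
    amplitude_cm: float = 10.0
    beat_sharpness: float = 2.0
    sensor_noise_sd_cm: float = 0.05

    def __post_init__(self):
        if self.beat_sharpness < 1.0:
            raise ParameterError("beat_sharpness must be >= 1")

    @classmethod
    def for_condition(cls, condition: str, **kw) -> "KinematicsParams":
        """Condition defaults: larger, slightly slower arm strokes; faster wrist."""
        base = {
            "wrist": dict(freq_mean=1.44, amplitude_cm=10.0),
            "arm": dict(freq_mean=1.36, amplitude_cm=25.0),
        }[condition]
        base.update(kw)
        return cls(**base)


@dataclass
class GroundTruth:
    """Everything injected into one synthetic trial."""

    condition: str
    duration_s: float
    fs: float = TRACK_FS
    beat_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    decel_onset_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    max_decel_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    env_bump_gains: np.ndarray = field(default_factory=lambda: np.empty(0))
    f0_bump_gains: np.ndarray = field(default_factory=lambda: np.empty(0))
    voiced_intervals: list = field(default_factory=list)
    true_f0: Optional[np.ndarray] = None  # NaN where unvoiced
    true_env: Optional[np.ndarray] = None

    @property
    def t(self) -> np.ndarray:
        n = int(round(self.duration_s * self.fs))
        return np.arange(n) / self.fs

    def env_track(self) -> EnvelopeTrack:
        return EnvelopeTrack(t=self.t, env=self.true_env, fs=self.fs)

    def f0_track(self) -> F0Track:
        return F0Track(t=self.t, f0=self.true_f0, fs=self.fs)

    def validate(self) -> None:
        if len(self.beat_times) and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.max_decel_values < 0):
            raise ValueError("max_decel must be nonnegative")


# ---------------------------------------------------------------------------
# kinematics

def _phase_warp(phi: np.ndarray, p: float) -> np.ndarray:
    """Warp cycle phase so the downstroke ends abruptly at the minimum.

    phi in [0, 1): 0 = top of stroke, 0.5 = bottom (maximum extension).
    Downstroke phase is raised to the power ``p`` (slow leave from the top,
    fast arrival at the bottom); the upstroke is left unwarped.  p = 1 is
    the identity (pure sinusoid).
    """
    u = phi.copy()
    down = phi < 0.5
    u[down] = 0.5 * (2.0 * phi[down]) ** p
    return u


def generate_kinematics(kp: KinematicsParams, duration_s: float,
                        rng_seed) -> tuple[MotionTrace, GroundTruth]:
    """Quasi-periodic beat waveform plus its kinematic ground truth.

    The per-sample frequency follows a slowly relaxing random walk around
    ``freq_mean``; truth (beat times, deceleration onsets and magnitudes)
    is computed on the noiseless trace before sensor noise is added.
    """
    if duration_s < 5.0:
        raise ParameterError("duration must be >= 5 s")
    rng = np.random.default_rng(rng_seed)
    fs = TRACK_FS
    n = int(round(duration_s * fs))
    dt = 1.0 / fs

    if kp.freq_sd > 0:
        # Ornstein-Uhlenbeck walk, relaxation ~5 s, stationary SD = freq_sd
        from scipy.signal import lfilter

        tau = 5.0
        a = 1.0 - dt / tau
        f_init = kp.freq_mean + rng.normal(0, kp.freq_sd)
        sig = kp.freq_sd * math.sqrt(2.0 * dt / tau)
        x = kp.freq_mean * dt / tau + rng.normal(0, sig, size=n - 1)
        y, _ = lfilter([1.0], [1.0, -a], x, zi=np.array([a * f_init]))
        f = np.concatenate([[f_init], y])
        f = np.clip(f, 0.4 * kp.freq_mean, 1.8 * kp.freq_mean)
    else:
        f = np.full(n, kp.freq_mean)

    phi0 = rng.uniform(0.0, 1.0)
    theta = phi0 + np.concatenate([[0.0], np.cumsum(f[:-1]) * dt])
    phi = np.mod(theta, 1.0)
    u = _phase_warp(phi, kp.beat_sharpness)
    z0 = kp.amplitude_cm * np.cos(2.0 * np.pi * u)

    t = np.arange(n) * dt
    beat_times = _phase_crossings(t, theta, 0.5)
    # only beats with a full measurement window inside the trace
    beat_times = beat_times[(beat_times >= 0.45) & (beat_times <= duration_s - 0.05)]

    v0 = np.gradient(z0, dt)
    a0 = np.gradient(v0, dt)
    onsets = np.empty(len(beat_times))
    decels = np.empty(len(beat_times))
    for k, tb in enumerate(beat_times):
        i1 = int(round(tb * fs))
        iw = max(0, i1 - int(round(0.2 * fs)))
        decels[k] = max(float(a0[iw:i1 + 1].max()), 0.0)
        io_ = max(0, i1 - int(round(0.4 * fs)))
        onsets[k] = t[io_ + int(np.argmin(v0[io_:i1 + 1]))]

    z = z0 + rng.normal(0.0, kp.sensor_noise_sd_cm, size=n)
    motion = MotionTrace(t=t, z=z, fs=fs)
    truth = GroundTruth(
        condition="", duration_s=duration_s, beat_times=beat_times,
        decel_onset_times=onsets, max_decel_values=decels,
    )
    return motion, truth


def _phase_crossings(t: np.ndarray, theta: np.ndarray, frac: float) -> np.ndarray:
    """Times where the unwrapped phase crosses ``k + frac`` (linear interp)."""
    s = theta - frac
    fl = np.floor(s)
    idx = np.nonzero(fl[1:] > fl[:-1])[0]
    times = []
    for i in idx:
        target = fl[i + 1]
        denom = s[i + 1] - s[i]
        w = (target - s[i]) / denom if denom > 0 else 0.0
        times.append(t[i] + w * (t[i + 1] - t[i]))
    return np.asarray(times)


# ---------------------------------------------------------------------------
# speech

def _smooth_noise(rng, n: int, sd: float, sigma_samples: float) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to the requested SD."""
    if sd <= 0 or n < 4:
        return np.zeros(n)
    x = gaussian_filter1d(rng.normal(0.0, 1.0, size=n), sigma_samples, mode="reflect")
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def _draw_durations(rng, mean_ms: float, sd_ms: float, total_ms: float,
                    other_mean_ms: float, other_sd_ms: float,
                    start_voiced: bool) -> list[tuple[float, float]]:
    """Alternating voiced intervals (s) from gamma-distributed run lengths."""

    def draw(mean, sd):
        if sd <= 0:
            return mean
        shape = (mean / sd) ** 2
        return float(rng.gamma(shape, scale=mean / shape))

    intervals = []
    pos = 0.0
    voiced = start_voiced
    while pos < total_ms:
        if voiced:
            d = max(30.0, draw(mean_ms, sd_ms))
            intervals.append((pos / 1000.0, min(pos + d, total_ms) / 1000.0))
        else:
            d = max(50.0, draw(other_mean_ms, other_sd_ms))
        pos += d
        voiced = not voiced
    return intervals


def generate_speech_tracks(sp: SpeakerParams, cp: CouplingParams,
                           truth: GroundTruth, condition: str,
                           duration_s: float, rng_seed) -> GroundTruth:
    """Complete a trial's ground truth with F0 and envelope contours.

    Baselines are f0_base/env_base plus participant intercept, slow drift,
    and jitter; at each beat a Gaussian bump of height
    ``mass_factor(condition) * beta * max_decel`` is added, centered
    ``bump_center_offset_ms`` before the maximum extension.  F0 is defined
    (and bumps have an acoustic trace) only inside voiced intervals; bumps
    falling wholly in pauses remain recorded in the truth.
    """
    if condition == "passive" and len(truth.beat_times):
        raise ParameterError("passive trials must have no beats")
    rng = np.random.default_rng(rng_seed)
    fs = TRACK_FS
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    intervals = _draw_durations(
        rng, sp.voiced_dur_mean_ms, sp.voiced_dur_sd_ms, duration_s * 1000.0,
        sp.pause_dur_mean_ms, sp.pause_dur_sd_ms,
        start_voiced=bool(rng.random() < 0.5),
    )
    voiced = np.zeros(n, dtype=bool)
    for on, off in intervals:
        voiced[int(round(on * fs)):int(round(off * fs))] = True

    f0 = (sp.f0_base + sp.f0_intercept + cp.f0_offset_hz.get(condition, 0.0)
          + _smooth_noise(rng, n, sp.f0_sd, sigma_samples=0.5 * fs)
          + _smooth_noise(rng, n, sp.f0_jitter_sd, sigma_samples=2.0))
    env = (sp.env_base + sp.env_intercept + cp.env_offset.get(condition, 0.0)
           + _smooth_noise(rng, n, sp.env_sd, sigma_samples=0.3 * fs)
           + _smooth_noise(rng, n, sp.env_jitter_sd, sigma_samples=2.0))
    env = np.clip(env, 0.02, None)

    mass = cp.mass_factor[condition]
    env_gains = mass * cp.beta_env * truth.max_decel_values
    f0_gains = mass * cp.beta_f0_for(condition) * truth.max_decel_values
    if len(truth.beat_times):
        sigma_s = cp.bump_width_ms / 1000.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        centers = truth.beat_times + cp.bump_center_offset_ms / 1000.0
        for tc, ge, gf in zip(centers, env_gains, f0_gains):
            lo = max(0, int((tc - 4 * sigma_s) * fs))
            hi = min(n, int((tc + 4 * sigma_s) * fs) + 1)
            if hi <= lo:
                continue
            bump = np.exp(-0.5 * ((t[lo:hi] - tc) / sigma_s) ** 2)
            env[lo:hi] += ge * bump
            f0[lo:hi] += gf * bump

    # the amplitude envelope is by construction a slow (<5 Hz) signal:
    # band-limit the masked contour with the same Hann convention the
    # extraction stage uses, so vocalization onsets ramp rather than step
    from scipy.signal import convolve, windows

    kern = windows.hann(int(round(fs / 5.0)))
    kern /= kern.sum()
    true_env = convolve(np.where(voiced, env, 0.0), kern, mode="same")
    true_env = np.clip(true_env, 0.0, None)
    true_f0 = np.where(voiced, f0, np.nan)

    out = replace(truth, condition=condition, duration_s=duration_s)
    out.voiced_intervals = intervals
    out.env_bump_gains = env_gains
    out.f0_bump_gains = f0_gains
    out.true_env = true_env
    out.true_f0 = true_f0
    return out


def render_audio(truth: GroundTruth, fs: float = io.AUDIO_FS,
                 rng_seed=0, noise_sd: float = 0.002) -> AudioTrack:
    """Render a trial's truth contours to audio.

    Harmonic complex (6 harmonics, 1/k roll-off) whose instantaneous
    frequency follows the true F0 inside voiced intervals, scaled by the
    true envelope, plus low-level noise in pauses; control contours are
    linearly interpolated up from 240 Hz.
    """
    if truth.true_env is None or truth.true_f0 is None:
        raise SynthesisError("truth has no speech contours")
    voiced_vals = truth.true_f0[np.isfinite(truth.true_f0)]
    if voiced_vals.size and (voiced_vals.min() < 30.0 or voiced_vals.max() > 1000.0):
        raise SynthesisError("true F0 outside [30, 1000] Hz")
    rng = np.random.default_rng(rng_seed)
    t_lo = truth.t
    n_hi = int(round(truth.duration_s * fs))
    t_hi = np.arange(n_hi) / fs

    env_hi = np.interp(t_hi, t_lo, truth.true_env)
    audio = rng.normal(0.0, noise_sd, size=n_hi)
    if voiced_vals.size:
        f0_filled = pd.Series(truth.true_f0).ffill().bfill().to_numpy()
        f0_hi = np.interp(t_hi, t_lo, f0_filled)
        phase = 2.0 * np.pi * np.cumsum(f0_hi) / fs
        nharm = 6
        wsum = sum(1.0 / k for k in range(1, nharm + 1))
        harm = np.zeros(n_hi)
        for k in range(1, nharm + 1):
            harm += np.sin(k * phase) / k
        harm /= wsum
        audio = env_hi * harm + audio
    peak = np.abs(audio).max()
    if peak > 0.99:
        audio *= 0.95 / peak
    return AudioTrack(samples=audio, fs=fs)


# ---------------------------------------------------------------------------
# sessions

@dataclass
class SimTrial:
    """One simulated trial, in memory (no files)."""

    participant_id: str
    sex: str
    condition: str
    trial_id: str
    motion: Optional[MotionTrace]
    truth: GroundTruth


def simulate_session(n_participants: int, trials_per_condition: int,
                     master_seed: int,
                     coupling: Optional[CouplingParams] = None,
                     duration_mean_s: float = 26.0,
                     duration_sd_s: float = 7.0,
                     kin_overrides: Optional[dict] = None,
                     speaker_overrides: Optional[dict] = None,
                     f0_intercept_sd: float = 10.0,
                     env_intercept_sd: float = 0.15) -> list[SimTrial]:
    """Simulate a full session in memory.

    Per-participant seeds derive deterministically from ``master_seed``;
    sex is assigned ~2:1 female:male; condition order is shuffled per
    participant; trial durations are drawn around 26 s (SD 7), clipped to
    [10, 40] s.
    """
    if n_participants < 1:
        raise ParameterError("need at least one participant")
    cp = coupling if coupling is not None else CouplingParams()
    master = np.random.SeedSequence(master_seed)
    part_seeds = master.spawn(n_participants)
    trials: list[SimTrial] = []
    for i, seed in enumerate(part_seeds):
        rng = np.random.default_rng(seed)
        pid = f"P{i + 1:03d}"
        sex = "male" if rng.random() < (1.0 / 3.0) else "female"
        sp = SpeakerParams.for_sex(
            sex,
            f0_intercept=float(rng.normal(0.0, f0_intercept_sd)),
            env_intercept=float(rng.normal(0.0, env_intercept_sd)),
            **(speaker_overrides or {}),
        )
        conditions = list(CONDITIONS) * trials_per_condition
        rng.shuffle(conditions)
        for j, cond in enumerate(conditions):
            dur = float(np.clip(rng.normal(duration_mean_s, duration_sd_s), 10.0, 40.0))
            tid = f"T{j + 1:02d}"
            kseed, sseed = rng.integers(0, 2**31, size=2)
            if cond == "passive":
                motion = None
                truth = GroundTruth(condition=cond, duration_s=dur)
            else:
                kp = KinematicsParams.for_condition(cond, **(kin_overrides or {}))
                motion, truth = generate_kinematics(kp, dur, kseed)
            truth = generate_speech_tracks(sp, cp, truth, cond, dur, sseed)
            trials.append(SimTrial(pid, sex, cond, tid, motion, truth))
    return trials


def generate_session(out_dir: Path, n_participants: int,
                     trials_per_condition: int, master_seed: int,
                     coupling: Optional[CouplingParams] = None,
                     duration_mean_s: float = 26.0, duration_sd_s: float = 7.0,
                     **kw) -> tuple[SessionManifest, dict[tuple, GroundTruth]]:
    """Simulate a session and write WAV + motion CSV + manifest + truth.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = simulate_session(
        n_participants, trials_per_condition, master_seed, coupling=coupling,
        duration_mean_s=duration_mean_s, duration_sd_s=duration_sd_s, **kw)
    entries = []
    truths: dict[tuple, GroundTruth] = {}
    truth_rows = []
    import zlib

    for tr in trials:
        stem = f"{tr.participant_id}_{tr.trial_id}"
        # process-independent per-trial render seed
        rseed = (master_seed * 1_000_003 + zlib.crc32(stem.encode())) % (2**31)
        audio = render_audio(tr.truth, rng_seed=rseed)
        wav = out_dir / f"{stem}.wav"
        io.write_wav(audio, wav)
        motion_path = None
        if tr.motion is not None:
            motion_path = out_dir / f"{stem}_motion.csv"
            io.write_motion_csv(tr.motion, motion_path)
        entries.append(TrialEntry(
            participant_id=tr.participant_id, sex=tr.sex, condition=tr.condition,
            trial_id=tr.trial_id, audio_path=wav, motion_path=motion_path,
        ))
        truths[(tr.participant_id, tr.trial_id)] = tr.truth
        for k in range(len(tr.truth.beat_times)):
            truth_rows.append({
                "participant_id": tr.participant_id, "trial_id": tr.trial_id,
                "condition": tr.condition, "cycle_index": k,
                "beat_time_s": tr.truth.beat_times[k],
                "decel_onset_s": tr.truth.decel_onset_times[k],
                "max_decel_cm_s2": tr.truth.max_decel_values[k],
                "env_bump_gain": tr.truth.env_bump_gains[k],
                "f0_bump_gain_hz": tr.truth.f0_bump_gains[k],
            })
    manifest = SessionManifest(entries)
    io.write_manifest(manifest, out_dir / "manifest.csv")
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return manifest, truths
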