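"""Speech-acoustics extraction: amplitude envelope, F0 track, vocalization events.

The amplitude envelope is the smoothed modulus of the analytic signal
(Hilbert transform), decimated to the 240-Hz grid shared with the motion
data.  F0 is tracked frame-wise by normalized autocorrelation with
sex-appropriate search ranges (male 50-400 Hz, female 80-640 Hz) and
octave-jump suppression; unvoiced frames are encoded as NaN.  A
*vocalization event* is an uninterrupted run of voiced frames; its
duration and the interval between consecutive events' envelope-peak
times are the two speech-rate measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io_session import AudioTrack

TRACK_FS = 240.0

#: F0 search ranges in Hz, by speaker sex
F0_RANGES = {"male": (50.0, 400.0), "female": (80.0, 640.0)}

#: default periodicity-strength threshold for the voicing decision
VOICING_THRESHOLD = 0.45


@dataclass
class EnvelopeTrack:
    """Amplitude envelope on the 240-Hz grid (nonnegative, arbitrary units)."""

    t: np.ndarray
    env: np.ndarray
    fs: float = TRACK_FS

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.env = np.asarray(self.env, dtype=float)
        if np.any(self.env < 0):
            raise ValueError("envelope must be nonnegative")

    def scaled(self, mean: float, sd: float) -> "EnvelopeTrack":
        """Return a z-scaled copy using participant-level statistics.

        z-scaling can produce negative values, so the result is returned as a
        bare-array pair on the same grid.
        """
        if sd <= 0:
            raise ValueError("degenerate envelope SD (all samples equal?)")
        out = EnvelopeTrack.__new__(EnvelopeTrack)
        out.t = self.t
        out.env = (self.env - mean) / sd
        out.fs = self.fs
        return out


@dataclass
class F0Track:
    """Fundamental frequency on the 240-Hz grid; NaN encodes unvoiced."""

    t: np.ndarray
    f0: np.ndarray
    fs: float = TRACK_FS

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)


@dataclass(frozen=True)
class VocalizationEvent:
    onset: float
    offset: float
    duration_ms: float
    peak_env_time: float
    peak_env_value: float
    max_f0: float


@dataclass
class TrialAcousticSummary:
    mean_f0: float
    mean_env_z: float
    voc_duration_hz: float
    voc_interval_hz: float
    n_events: int


def compute_envelope(audio: AudioTrack, smooth_hz: float = 5.0,
                     out_fs: float = TRACK_FS) -> EnvelopeTrack:
    """Smoothed Hilbert amplitude envelope, decimated to ``out_fs``.

    The modulus of the analytic signal is convolved with a Hann kernel of
    duration ``1/smooth_hz`` seconds and resampled to the output grid by
    polyphase decimation (anti-aliased).
    """
    x = np.asarray(audio.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty audio")
    fs = audio.fs
    # pad to a power-of-two FFT length for the Hilbert transform
    n = len(x)
    nfft = int(2 ** math.ceil(math.log2(max(n, 2))))
    analytic = sps.hilbert(x, N=nfft)[:n]
    env = np.abs(analytic)

    klen = max(3, int(round(fs / smooth_hz)))
    kern = sps.windows.hann(klen)
    kern /= kern.sum()
    env = sps.convolve(env, kern, mode="same")

    frac = Fraction(int(round(out_fs)), int(round(fs))).limit_denominator(10000)
    env240 = sps.resample_poly(env, frac.numerator, frac.denominator)
    env240 = np.clip(env240, 0.0, None)
    t = np.arange(len(env240)) / out_fs
    return EnvelopeTrack(t=t, env=env240, fs=out_fs)


def _frame_matrix(x: np.ndarray, centers: np.ndarray, win: int) -> np.ndarray:
    """Gather frames of length ``win`` centered on sample indices ``centers``."""
    half = win // 2
    idx = centers[:, None] + np.arange(-half, win - half)[None, :]
    idx = np.clip(idx, 0, len(x) - 1)
    return x[idx]


def track_f0(audio: AudioTrack, sex: str,
             voicing_threshold: float = VOICING_THRESHOLD,
             out_fs: float = TRACK_FS,
             analysis_fs: float = 11025.0) -> F0Track:
    """Frame-wise autocorrelation F0 tracking on the 240-Hz grid.

    Frames whose normalized-autocorrelation peak falls below
    ``voicing_threshold`` (or whose best period lies outside the
    sex-appropriate range) are unvoiced (NaN).  Within voiced runs,
    frame-to-frame jumps above 40% are suppressed by re-picking the
    autocorrelation candidate nearest the locally median-filtered track.
    """
    if sex not in F0_RANGES:
        raise ValueError(f"unknown sex label {sex!r}")
    fmin, fmax = F0_RANGES[sex]
    x = np.asarray(audio.samples, dtype=float)
    if x.size == 0:
        return F0Track(t=np.empty(0), f0=np.empty(0), fs=out_fs)

    # decimate for speed; the range ceiling (640 Hz) is far below Nyquist
    dec = max(1, int(round(audio.fs / analysis_fs)))
    if dec > 1:
        x = sps.decimate(x, dec, zero_phase=True)
    fs = audio.fs / dec

    win = int(round(0.040 * fs))  # 40 ms: >= 2 periods of the lowest male F0
    n_frames = int(math.floor(len(x) / fs * out_fs))
    if n_frames == 0:
        return F0Track(t=np.empty(0), f0=np.empty(0), fs=out_fs)
    centers = np.round(np.arange(n_frames) / out_fs * fs).astype(int)
    frames = _frame_matrix(x, centers, win)
    frames = frames - frames.mean(axis=1, keepdims=True)

    nfft = int(2 ** math.ceil(math.log2(2 * win)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, axis=1)[:, :win]
    e0 = ac[:, 0]
    quiet = e0 < 1e-12
    norm = np.where(quiet, 1.0, e0)
    r = ac / norm[:, None]
    # unbiased lag normalization: undo the (1 - tau/N) shrinkage of the
    # windowed autocorrelation so long-period (low-F0) peaks compete
    # fairly; clipped so the tail of the window is not noise-amplified
    r = r / np.maximum(1.0 - np.arange(win) / win, 0.4)[None, :]

    lag_min = max(2, int(math.floor(fs / fmax)))
    lag_max = min(win - 2, int(math.ceil(fs / fmin)))
    if lag_max <= lag_min:
        raise ValueError("analysis window too short for the requested F0 range")

    band = r[:, lag_min:lag_max + 1]
    band_max = band.max(axis=1)
    # candidate periods are local maxima of the autocorrelation; among
    # near-equal candidates prefer the shortest lag, because the unbiased
    # lag normalization can push a subharmonic (octave-down) peak
    # marginally above the true period
    interior = band[:, 1:-1]
    is_peak = (interior >= band[:, :-2]) & (interior >= band[:, 2:])
    good = is_peak & (interior >= (band_max[:, None] - 0.04))
    has_peak = good.any(axis=1)
    best = np.where(has_peak, np.argmax(good, axis=1) + 1,
                    np.argmax(band, axis=1)) + lag_min
    strength = r[np.arange(n_frames), best]

    # parabolic interpolation of the autocorrelation peak for sub-sample lags
    l0 = best
    rm = r[np.arange(n_frames), np.clip(l0 - 1, 0, win - 1)]
    rc = r[np.arange(n_frames), l0]
    rp = r[np.arange(n_frames), np.clip(l0 + 1, 0, win - 1)]
    denom = rm - 2 * rc + rp
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (rm - rp) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    lag = l0 + shift

    f0 = fs / lag
    # frames whose full analysis window does not fit inside the signal are
    # edge-padded and unreliable; treat them as unvoiced
    half = win // 2
    full_window = (centers - half >= 0) & (centers + (win - half) <= len(x))
    voiced = ((strength >= voicing_threshold) & ~quiet & full_window
              & (f0 >= fmin) & (f0 <= fmax))

    # consistency with the unconstrained autocorrelation maximum: a frame
    # whose global periodicity peak (searched beyond the zero-lag main
    # lobe) is much stronger than the in-range peak and sits at a
    # non-multiple lag has its true fundamental outside the search range
    # (e.g. a male-register tone under a female floor)
    has_neg = (r < 0).any(axis=1)
    first_neg = np.argmax(r < 0, axis=1)
    cols = np.arange(win)[None, :]
    lag_hi_g = min(win - 1, int(fs / 40.0))  # no voice below 40 Hz
    mask = (cols >= first_neg[:, None]) & (cols < lag_hi_g) & has_neg[:, None]
    r_masked = np.where(mask, r, -np.inf)
    best_g = np.argmax(r_masked, axis=1)
    strength_g = np.where(has_neg, r[np.arange(n_frames), best_g], -np.inf)
    ratio = best_g / np.maximum(lag, 1e-9)
    near_multiple = ((np.abs(ratio - np.round(ratio)) < 0.15)
                     & (np.round(ratio) <= 4) & (np.round(ratio) >= 1))
    consistent = near_multiple | (strength >= strength_g - 0.08) | ~has_neg
    voiced &= consistent

    f0 = np.where(voiced, f0, np.nan)

    f0 = _suppress_octave_jumps(f0, r, fs, (fmin, fmax), voicing_threshold)

    t = np.arange(n_frames) / out_fs
    return F0Track(t=t, f0=f0, fs=out_fs)


def _suppress_octave_jumps(f0: np.ndarray, r: np.ndarray, fs: float,
                           frange: tuple, threshold: float) -> np.ndarray:
    """Re-pick frames deviating >40% from the local median of their voiced run."""
    out = f0.copy()
    voiced = np.isfinite(out)
    if voiced.sum() < 3:
        return out
    fmin, fmax = frange
    runs = _runs(voiced)
    win = r.shape[1]
    for i0, i1 in runs:
        seg = out[i0:i1]
        if len(seg) < 3:
            continue
        ks = min(5, len(seg) if len(seg) % 2 else len(seg) - 1)
        med = sps.medfilt(seg, kernel_size=ks)
        bad = np.abs(seg - med) > 0.4 * med
        for j in np.nonzero(bad)[0]:
            target = med[j]
            # candidate periods at the fundamental and octave alternatives
            cands = [target, target / 2, target * 2]
            bestf, bestr = seg[j], -np.inf
            for c in cands:
                if not (fmin <= c <= fmax):
                    continue
                lag = int(round(fs / c))
                if not (1 <= lag < win):
                    continue
                val = r[i0 + j, lag]
                if val > bestr and val >= 0.8 * threshold:
                    bestr, bestf = val, fs / lag
            if np.isfinite(bestr) and abs(bestf - target) < abs(seg[j] - target):
                seg[j] = bestf
        out[i0:i1] = seg
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def segment_vocalizations(f0: F0Track, env: EnvelopeTrack,
                          min_gap_ms: float = 0.0) -> list[VocalizationEvent]:
    """Maximal voiced runs as vocalization events.

    Runs separated by fewer than ``min_gap_ms`` of unvoiced frames are
    merged (default 0: strict uninterrupted runs).  Each event carries its
    duration, the time and value of its envelope peak, and its maximum F0.
    """
    if len(f0.f0) != len(env.env):
        raise ValueError("f0 and envelope must share a grid")
    voiced = f0.voiced
    runs = _runs(voiced)
    if not runs:
        return []
    dt = 1.0 / f0.fs
    if min_gap_ms > 0 and len(runs) > 1:
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            gap_ms = (s - merged[-1][1]) * dt * 1000.0
            if gap_ms < min_gap_ms:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [tuple(m) for m in merged]
    events = []
    for s, e in runs:
        onset = f0.t[s]
        offset = onset + (e - s) * dt
        seg_env = env.env[s:e]
        k = int(np.argmax(seg_env))
        seg_f0 = f0.f0[s:e]
        events.append(
            VocalizationEvent(
                onset=onset,
                offset=offset,
                duration_ms=(e - s) * dt * 1000.0,
                peak_env_time=env.t[s + k],
                peak_env_value=float(seg_env[k]),
                max_f0=float(np.nanmax(seg_f0)) if np.any(np.isfinite(seg_f0)) else np.nan,
            )
        )
    return events


def participant_env_stats(envs: list[EnvelopeTrack],
                          f0s: Optional[list[F0Track]] = None) -> tuple[float, float]:
    """Pooled envelope mean/SD for one participant (voiced frames if F0 given).

    Pooled across all of that participant's trials and conditions, so the
    z-scale preserves between-condition differences.
    """
    samples = []
    for i, e in enumerate(envs):
        v = e.env
        if f0s is not None:
            v = v[f0s[i].voiced]
        samples.append(v)
    pooled = np.concatenate(samples) if samples else np.empty(0)
    if pooled.size == 0:
        return np.nan, np.nan
    return float(pooled.mean()), float(pooled.std())


def trial_acoustic_summary(events: list[VocalizationEvent], f0: F0Track,
                           env: EnvelopeTrack,
                           participant_env_stats: tuple[float, float]
                           ) -> TrialAcousticSummary:
    """Per-trial acoustic summary feeding the condition-contrast models.

    Rates are converted from milliseconds to hertz (1000 / mean duration);
    the envelope mean is z-scaled with participant-level statistics and,
    like mean F0, is taken over voiced frames only.
    """
    mu, sd = participant_env_stats
    if sd is not None and sd == 0:
        raise ValueError("degenerate envelope SD for participant (all samples equal)")
    voiced = f0.voiced
    if len(events) == 0 or not np.any(voiced):
        return TrialAcousticSummary(np.nan, np.nan, np.nan, np.nan, 0)
    mean_f0 = float(np.nanmean(f0.f0[voiced]))
    mean_env_z = float((env.env[voiced].mean() - mu) / sd)
    durations = np.array([ev.duration_ms for ev in events])
    voc_duration_hz = 1000.0 / durations.mean()
    if len(events) >= 2:
        peaks = np.array([ev.peak_env_time for ev in events])
        intervals_ms = np.diff(peaks) * 1000.0
        voc_interval_hz = 1000.0 / intervals_ms.mean()
    else:
        voc_interval_hz = np.nan
    return TrialAcousticSummary(mean_f0, mean_env_z, voc_duration_hz,
                                voc_interval_hz, len(events))
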