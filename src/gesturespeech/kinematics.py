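"""Kinematic processing: filtering, beat detection, deceleration, tempo.

Sign conventions: z increases upward, so the instructed downstroke has
negative velocity and its braking (the beat's "sudden halt" at maximum
extension, the position minimum) appears as positive acceleration.
``max_decel`` is reported absolutized (>= 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .io_session import MotionTrace

#: first-order Butterworth cutoff used for position and derivatives, Hz
DEFAULT_CUTOFF_HZ = 30.0

#: the study's target tempo and feedback-region width
TARGET_TEMPO_BPM = 80.0
TARGET_FREQ_HZ = 1.33  # the 80-BPM target as conventionally stated in Hz
REGION_FRACTION = 0.2

#: deceleration measurement window before maximum extension, ms
DECEL_WINDOW_MS = 200.0


def cycle_period_ms(freq_hz: float) -> float:
    """Duration of one movement cycle in ms (e.g. 1000 / 1.33 = 752 ms)."""
    return 1000.0 / freq_hz


def tempo_region_bpm(target_bpm: float = TARGET_TEMPO_BPM,
                     region_fraction: float = REGION_FRACTION) -> tuple[float, float]:
    """Feedback-region bounds around the target tempo (80 BPM, 20% -> 72-88)."""
    half = region_fraction / 2.0
    return target_bpm * (1.0 - half), target_bpm * (1.0 + half)


@dataclass
class KinematicDerivatives:
    t: np.ndarray
    z_f: np.ndarray  # filtered position, cm
    v: np.ndarray    # cm/s
    a: np.ndarray    # cm/s^2
    fs: float


@dataclass
class BeatEvent:
    t_ext: float             # maximum extension (position minimum), s
    cycle_index: int
    t_decel_onset: float = np.nan
    max_decel: float = np.nan  # absolutized, cm/s^2
    valid: bool = True         # False when too close to the trace edge


@dataclass
class FrequencyEstimate:
    t: np.ndarray
    freq: np.ndarray
    trial_mean: float
    trial_sd: float
    compliance: float  # fraction of ridge samples inside the target region


def smooth_and_differentiate(motion: MotionTrace,
                             cutoff_hz: float = DEFAULT_CUTOFF_HZ
                             ) -> KinematicDerivatives:
    """Zero-phase first-order low-pass, then central-difference derivatives.

    Position is filtered, differentiated, and each derivative re-filtered
    with the same filter (symmetric noise control).  Forward-backward
    application keeps event times unshifted.
    """
    fs = motion.fs
    if fs <= 2.0 * cutoff_hz:
        raise ValueError(f"sampling rate {fs} Hz too low for a {cutoff_hz}-Hz cutoff")
    b, a = sps.butter(1, cutoff_hz, fs=fs)
    dt = 1.0 / fs
    z_f = sps.filtfilt(b, a, motion.z)
    v = sps.filtfilt(b, a, np.gradient(z_f, dt))
    acc = sps.filtfilt(b, a, np.gradient(v, dt))
    return KinematicDerivatives(t=motion.t, z_f=z_f, v=v, a=acc, fs=fs)


def detect_max_extensions(kin: KinematicDerivatives,
                          min_period_s: float = 0.4,
                          min_amplitude_cm: float = 2.0) -> list[BeatEvent]:
    """Maximum extensions as local minima of the filtered position.

    Candidate minima must be separated by at least ``min_period_s`` and
    have a peak-to-peak excursion of at least ``min_amplitude_cm`` within
    the enclosing cycle (enforced via peak prominence).
    """
    z = kin.z_f
    if len(z) < 3 or np.ptp(z) < min_amplitude_cm:
        return []
    distance = max(1, int(round(min_period_s * kin.fs)))
    idx, _ = sps.find_peaks(-z, distance=distance, prominence=min_amplitude_cm / 2.0)
    dt = 1.0 / kin.fs
    events = []
    for k, i in enumerate(idx):
        t_ext = kin.t[i]
        if 0 < i < len(z) - 1:
            # sub-sample refinement: parabola through the minimum sample
            denom = z[i - 1] - 2 * z[i] + z[i + 1]
            if denom > 1e-12:
                shift = 0.5 * (z[i - 1] - z[i + 1]) / denom
                t_ext = t_ext + np.clip(shift, -0.5, 0.5) * dt
        events.append(BeatEvent(t_ext=float(t_ext), cycle_index=k))
    return events


def annotate_deceleration(kin: KinematicDerivatives, events: list[BeatEvent],
                          window_ms: float = DECEL_WINDOW_MS) -> list[BeatEvent]:
    """Attach deceleration onset and magnitude to each beat.

    ``t_decel_onset`` is the time of maximum downward speed (the velocity
    minimum) in the 400 ms preceding the extension -- on a pure sinusoid
    this lies a quarter period before the position minimum.  ``max_decel``
    is the largest acceleration opposing the downstroke within
    ``[t_ext - window, t_ext]``, absolutized.
    """
    fs = kin.fs
    n = len(kin.z_f)
    wlen = int(round(window_ms / 1000.0 * fs))
    search = int(round(0.4 * fs))
    out = []
    for ev in events:
        i1 = int(round(ev.t_ext * fs))
        i1 = min(max(i1, 0), n - 1)
        if ev.t_ext < 0.4 or i1 - search < 0:
            out.append(BeatEvent(t_ext=ev.t_ext, cycle_index=ev.cycle_index,
                                 valid=False))
            continue
        iw = i1 - wlen
        max_decel = max(float(kin.a[iw:i1 + 1].max()), 0.0)
        i_on = (i1 - search) + int(np.argmin(kin.v[i1 - search:i1 + 1]))
        out.append(BeatEvent(
            t_ext=ev.t_ext, cycle_index=ev.cycle_index,
            t_decel_onset=float(kin.t[i_on]), max_decel=max_decel, valid=True,
        ))
    return out


def estimate_movement_frequency(kin: KinematicDerivatives,
                                target_hz: float = TARGET_FREQ_HZ,
                                region_fraction: float = REGION_FRACTION,
                                freq_lo: float = 0.6, freq_hi: float = 3.0,
                                n_freqs: int = 60,
                                edge_trim_s: float = 1.0) -> FrequencyEstimate:
    """Time-varying movement frequency from a Morlet wavelet ridge.

    The ridge is the per-time power argmax of a complex-Morlet continuous
    wavelet transform over ``freq_lo``-``freq_hi`` Hz.  Compliance is the
    fraction of (edge-trimmed) ridge samples inside the target region
    ``target * (1 +/- region_fraction / 2)``.
    """
    fs = kin.fs
    n = len(kin.z_f)
    if n / fs < 3.0 / freq_lo:
        raise ValueError("trace shorter than 3 cycles at the lowest analyzed frequency")
    freqs = np.geomspace(freq_lo, freq_hi, n_freqs)
    wavelet = "cmor1.5-1.0"
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    x = kin.z_f - kin.z_f.mean()
    coef, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / fs)
    power = np.abs(coef) ** 2
    ridge = freqs[np.argmax(power, axis=0)]
    trim = int(round(edge_trim_s * fs))
    core = ridge[trim:n - trim] if n > 2 * trim else ridge
    lo = target_hz * (1.0 - region_fraction / 2.0)
    hi = target_hz * (1.0 + region_fraction / 2.0)
    compliance = float(np.mean((core >= lo) & (core <= hi))) if core.size else np.nan
    return FrequencyEstimate(
        t=kin.t, freq=ridge,
        trial_mean=float(core.mean()) if core.size else np.nan,
        trial_sd=float(core.std()) if core.size else np.nan,
        compliance=compliance,
    )
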