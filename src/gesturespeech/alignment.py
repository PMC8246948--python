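"""Beat-locked alignment: epochs, trajectory averages, surrogate baseline,
and impulse-window features.

Epochs slice the acoustic tracks onto a fixed relative-time grid around
each maximum extension (-400 to +400 ms at 240 Hz: 193 samples, rel_t = 0
at the extension).  The surrogate baseline re-pairs passive-condition
speech with movement-condition beats from the same participant, preserving
within-trial temporal order, to estimate what beat-locked structure arises
by chance.  Impulse-window features pair each beat's maximum deceleration
with the acoustic maxima of vocalizations overlapping the 200 ms before
the extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .acoustics import EnvelopeTrack, F0Track, VocalizationEvent
from .kinematics import BeatEvent

log = logging.getLogger(__name__)

EPOCH_WINDOW_MS = (-400.0, 400.0)
IMPULSE_WINDOW_MS = (-200.0, 0.0)


def epoch_grid_ms(window_ms: tuple = EPOCH_WINDOW_MS, fs: float = 240.0) -> np.ndarray:
    """The fixed relative-time grid shared by all epochs (193 samples)."""
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    return np.arange(lo, hi + 1) / fs * 1000.0


@dataclass
class Epoch:
    rel_t_ms: np.ndarray
    env: np.ndarray
    f0: np.ndarray
    t_ext: float
    cycle_index: int
    condition: str = ""
    participant_id: str = ""
    trial_id: str = ""


@dataclass
class SurrogatePairing:
    pairs: list  # (participant_id, passive_trial_id, donor_trial_id)
    pairing_seed: int


@dataclass
class AnalyzedTrial:
    """Per-trial inputs to alignment: tracks plus annotated beats."""

    participant_id: str
    sex: str
    trial_id: str
    condition: str
    env: EnvelopeTrack
    f0: F0Track
    beats: list = field(default_factory=list)
    events: list = field(default_factory=list)


def extract_epochs(beats: Sequence[BeatEvent], env: EnvelopeTrack, f0: F0Track,
                   window_ms: tuple = EPOCH_WINDOW_MS) -> list[Epoch]:
    """One epoch per beat whose full window lies inside the trial.

    Tracks are sliced by nearest-grid alignment (no interpolation); F0
    retains its unvoiced NaNs.  Beats within the half-window of either
    trial edge are skipped (logged).
    """
    if len(env.env) != len(f0.f0):
        raise ValueError("envelope and F0 tracks must share a grid")
    fs = env.fs
    grid = epoch_grid_ms(window_ms, fs)
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    n = len(env.env)
    epochs, skipped = [], 0
    for ev in beats:
        if isinstance(ev, BeatEvent) and not ev.valid:
            skipped += 1
            continue
        t_ext = ev.t_ext if isinstance(ev, BeatEvent) else float(ev)
        ci = ev.cycle_index if isinstance(ev, BeatEvent) else len(epochs)
        i0 = int(round(t_ext * fs))
        if i0 + lo < 0 or i0 + hi >= n:
            skipped += 1
            continue
        sl = slice(i0 + lo, i0 + hi + 1)
        epochs.append(Epoch(rel_t_ms=grid, env=env.env[sl].copy(),
                            f0=f0.f0[sl].copy(), t_ext=t_ext, cycle_index=ci))
    if skipped:
        log.info("extract_epochs: skipped %d beats at trial edges", skipped)
    return epochs


def trial_epochs(trial: AnalyzedTrial,
                 window_ms: tuple = EPOCH_WINDOW_MS) -> list[Epoch]:
    eps = extract_epochs(trial.beats, trial.env, trial.f0, window_ms)
    for e in eps:
        e.condition = trial.condition
        e.participant_id = trial.participant_id
        e.trial_id = trial.trial_id
    return eps


def epochs_to_frame(epochs: Sequence[Epoch]) -> pd.DataFrame:
    """Long-format epochs table: one row per (epoch, rel_t) sample."""
    if not epochs:
        return pd.DataFrame(columns=["participant_id", "trial_id", "condition",
                                     "cycle_index", "rel_t_ms", "env", "f0"])
    m = len(epochs[0].rel_t_ms)
    return pd.DataFrame({
        "participant_id": np.repeat([e.participant_id for e in epochs], m),
        "trial_id": np.repeat([e.trial_id for e in epochs], m),
        "condition": np.repeat([e.condition for e in epochs], m),
        "cycle_index": np.repeat([e.cycle_index for e in epochs], m),
        "rel_t_ms": np.tile(epochs[0].rel_t_ms, len(epochs)),
        "env": np.concatenate([e.env for e in epochs]),
        "f0": np.concatenate([e.f0 for e in epochs]),
    })


def average_trajectories(epochs_df: pd.DataFrame,
                         group_keys: Sequence[str] = ("condition",),
                         values: Sequence[str] = ("env", "f0")) -> pd.DataFrame:
    """Pointwise mean +/- SE per group over the rel_t grid (NaNs ignored)."""
    keys = list(group_keys) + ["rel_t_ms"]
    out = []
    for val in values:
        g = epochs_df.groupby(keys, observed=True)[val]
        agg = g.agg(["mean", "sem", "count"]).reset_index()
        agg["signal"] = val
        out.append(agg.rename(columns={"sem": "se", "count": "n"}))
    return pd.concat(out, ignore_index=True)


def build_surrogate(trials: Sequence[AnalyzedTrial], pairing_seed: int,
                    window_ms: tuple = EPOCH_WINDOW_MS
                    ) -> tuple[SurrogatePairing, list[Epoch]]:
    """Random within-participant pairing of passive speech with movement beats.

    Each passive trial's acoustic tracks are epoched on the beat times of a
    uniformly drawn (seeded) same-participant movement trial; donor beats
    beyond the speech trial's duration are discarded; temporal order is
    never permuted.  Participants lacking a passive or a movement trial are
    excluded (logged).
    """
    rng = np.random.default_rng(pairing_seed)
    by_part: dict[str, dict[str, list]] = {}
    for tr in trials:
        d = by_part.setdefault(tr.participant_id, {"passive": [], "movement": []})
        d["passive" if tr.condition == "passive" else "movement"].append(tr)
    pairs, epochs = [], []
    for pid in sorted(by_part):
        d = by_part[pid]
        if not d["passive"] or not d["movement"]:
            log.info("surrogate: participant %s lacks a required condition", pid)
            continue
        for sp_trial in d["passive"]:
            donor = d["movement"][rng.integers(len(d["movement"]))]
            pairs.append((pid, sp_trial.trial_id, donor.trial_id))
            dur = len(sp_trial.env.env) / sp_trial.env.fs
            beats = [b for b in donor.beats
                     if b.valid and b.t_ext <= dur - window_ms[1] / 1000.0]
            eps = extract_epochs(beats, sp_trial.env, sp_trial.f0, window_ms)
            for e in eps:
                e.condition = "surrogate"
                e.participant_id = pid
                e.trial_id = sp_trial.trial_id
            epochs.extend(eps)
    return SurrogatePairing(pairs=pairs, pairing_seed=pairing_seed), epochs


def impulse_window_features(beats: Sequence[BeatEvent],
                            events: Sequence[VocalizationEvent],
                            env: EnvelopeTrack, f0: F0Track,
                            window_ms: tuple = IMPULSE_WINDOW_MS) -> pd.DataFrame:
    """One observation per (beat, overlapping vocalization) pair.

    Acoustic maxima are taken over the closed intersection of the
    vocalization and the deceleration window ``[t_ext - 200 ms, t_ext]``;
    ``max_decel`` comes from the beat annotation.  Vocalizations with no
    overlap contribute nothing.
    """
    fs = env.fs
    rows = []
    for b in beats:
        if not b.valid or not np.isfinite(b.max_decel):
            continue
        w0 = b.t_ext + window_ms[0] / 1000.0
        w1 = b.t_ext + window_ms[1] / 1000.0
        for vi, ev in enumerate(events):
            o0, o1 = max(ev.onset, w0), min(ev.offset, w1)
            if o1 < o0:
                continue
            i0 = int(np.ceil(o0 * fs - 1e-9))
            i1 = int(np.floor(o1 * fs + 1e-9))
            i0, i1 = max(i0, 0), min(i1, len(env.env) - 1)
            if i1 < i0:
                continue
            seg_env = env.env[i0:i1 + 1]
            seg_f0 = f0.f0[i0:i1 + 1]
            rows.append({
                "cycle_index": b.cycle_index,
                "vocalization_id": vi,
                "max_decel": b.max_decel,
                "max_env": float(np.max(seg_env)),
                "max_f0": (float(np.nanmax(seg_f0))
                           if np.any(np.isfinite(seg_f0)) else np.nan),
            })
    return pd.DataFrame(rows, columns=["cycle_index", "vocalization_id",
                                       "max_decel", "max_env", "max_f0"])


def aggregate_impulse_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Trial-level means of max deceleration and acoustic maxima."""
    keys = ["participant_id", "trial_id", "condition"]
    if obs.empty:
        return pd.DataFrame(columns=keys + ["max_decel", "max_env", "max_f0", "n_obs"])
    g = obs.groupby(keys, observed=True)
    out = g[["max_decel", "max_env", "max_f0"]].mean().reset_index()
    out["n_obs"] = g.size().to_numpy()
    return out
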