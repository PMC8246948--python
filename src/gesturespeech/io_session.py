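"""Session I/O: WAV audio, motion-capture CSV, and session manifests.

A *session* is one recording run: a manifest CSV listing trials, one mono
WAV file per trial, and (for movement trials) one motion CSV holding the
vertical position of the index-finger sensor.  The manifest is the single
source of truth for condition labels.

Motion CSV dialect (a repository convention, not a claim about any archive
layout): columns ``time_ms, x_cm, y_cm, z_cm``; only ``z_cm`` is consumed
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

AUDIO_FS = 44100.0
MOTION_FS = 240.0

CONDITIONS = ("passive", "wrist", "arm")
SEXES = ("male", "female")

#: movement conditions carry a motion trace; passive does not
MOVEMENT_CONDITIONS = ("wrist", "arm")


class SessionValidationError(ValueError):
    """Manifest or trial data violates the session schema."""


@dataclass(frozen=True)
class TrialEntry:
    participant_id: str
    sex: str
    condition: str
    trial_id: str
    audio_path: Path
    motion_path: Optional[Path] = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SessionValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.sex not in SEXES:
            raise SessionValidationError(
                f"unknown sex {self.sex!r}; expected one of {SEXES}"
            )
        if self.condition == "passive" and self.motion_path is not None:
            raise SessionValidationError(
                f"passive trial {self.trial_id!r} has a motion path "
                "(mislabeled condition?)"
            )
        if self.condition in MOVEMENT_CONDITIONS and self.motion_path is None:
            raise SessionValidationError(
                f"{self.condition} trial {self.trial_id!r} lacks a motion path"
            )


@dataclass
class SessionManifest:
    entries: list[TrialEntry] = field(default_factory=list)

    def __post_init__(self):
        keys = [(e.participant_id, e.trial_id) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise SessionValidationError("duplicate (participant_id, trial_id) pairs")

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class AudioTrack:
    """Mono audio, normalized amplitude (dimensionless)."""

    samples: np.ndarray
    fs: float = AUDIO_FS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise SessionValidationError("audio must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise SessionValidationError("audio contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class MotionTrace:
    """Vertical position of the limb sensor in cm, uniformly sampled."""

    t: np.ndarray
    z: np.ndarray
    fs: float = MOTION_FS

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.t.shape != self.z.shape:
            raise SessionValidationError("motion t and z length mismatch")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            period = 1.0 / self.fs
            if np.any(dt <= 0):
                raise SessionValidationError("motion timestamps not increasing")
            # tolerate jitter up to one sample period (dropped samples show up
            # as gaps of >= 2 periods)
            if np.any(np.abs(dt - period) > period):
                raise SessionValidationError(
                    "non-uniform motion sampling beyond one sample period "
                    "(dropped samples?)"
                )

    @property
    def duration_s(self) -> float:
        return len(self.z) / self.fs


@dataclass
class TrialRecord:
    entry: TrialEntry
    audio: AudioTrack
    motion: Optional[MotionTrace] = None

    def __post_init__(self):
        if self.audio.duration_s <= 0:
            raise SessionValidationError("empty audio")
        if self.motion is not None:
            if abs(self.motion.duration_s - self.audio.duration_s) > 1.0:
                raise SessionValidationError(
                    "motion and audio durations differ by more than 1 s"
                )


# ---------------------------------------------------------------------------
# readers / writers

_MANIFEST_COLS = ["participant_id", "sex", "condition", "trial_id", "audio_path", "motion_path"]


def write_manifest(manifest: SessionManifest, path: Path) -> None:
    """Write the manifest CSV; data paths are stored relative to it."""
    import os

    root = Path(path).parent

    def rel(p):
        p = Path(p)
        return os.path.relpath(p, root) if p.is_absolute() else str(p)

    rows = []
    for e in manifest:
        rows.append(
            {
                "participant_id": e.participant_id,
                "sex": e.sex,
                "condition": e.condition,
                "trial_id": e.trial_id,
                "audio_path": rel(e.audio_path),
                "motion_path": "" if e.motion_path is None else rel(e.motion_path),
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(path, index=False)


def load_session(manifest_path: Path, check_files: bool = True) -> SessionManifest:
    """Load and validate a session manifest CSV.

    Raises
    ------
    FileNotFoundError
        Missing manifest, or (``check_files=True``) a referenced data file.
    SessionValidationError
        Unknown condition/sex labels, duplicate trials, or a passive entry
        carrying a motion path.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    missing = set(_MANIFEST_COLS) - set(df.columns)
    if missing:
        raise SessionValidationError(f"manifest missing columns: {sorted(missing)}")
    root = manifest_path.parent
    entries = []
    for row in df.itertuples(index=False):
        motion = row.motion_path or None
        entry = TrialEntry(
            participant_id=row.participant_id,
            sex=row.sex,
            condition=row.condition,
            trial_id=row.trial_id,
            audio_path=root / row.audio_path,
            motion_path=None if motion is None else root / motion,
        )
        if check_files:
            if not entry.audio_path.exists():
                raise FileNotFoundError(entry.audio_path)
            if entry.motion_path is not None and not entry.motion_path.exists():
                raise FileNotFoundError(entry.motion_path)
        entries.append(entry)
    return SessionManifest(entries)


def write_wav(audio: AudioTrack, path: Path) -> None:
    """Write 16-bit PCM mono WAV."""
    x = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(path, int(audio.fs), np.round(x * 32767.0).astype(np.int16))


def read_wav(path: Path) -> AudioTrack:
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise SessionValidationError(f"{path}: stereo audio not supported")
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:  # float WAV
        samples = data.astype(float)
    return AudioTrack(samples=samples, fs=float(fs))


def write_motion_csv(motion: MotionTrace, path: Path) -> None:
    n = len(motion.z)
    zeros = np.zeros(n)
    pd.DataFrame(
        {
            "time_ms": motion.t * 1000.0,
            "x_cm": zeros,
            "y_cm": zeros,
            "z_cm": motion.z,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_motion_csv(path: Path, fs: float = MOTION_FS) -> MotionTrace:
    df = pd.read_csv(path)
    for col in ("time_ms", "z_cm"):
        if col not in df.columns:
            raise SessionValidationError(f"{path}: missing column {col!r}")
    return MotionTrace(t=df["time_ms"].to_numpy() / 1000.0, z=df["z_cm"].to_numpy(), fs=fs)


def load_trial(entry: TrialEntry) -> TrialRecord:
    """Load one trial's audio (and motion, for movement conditions)."""
    audio = read_wav(entry.audio_path)
    motion = None
    if entry.motion_path is not None:
        motion = read_motion_csv(entry.motion_path)
    return TrialRecord(entry=entry, audio=audio, motion=motion)


def write_table(df: pd.DataFrame, path: Path) -> None:
    """Write a tidy result table as CSV (the pipeline's only output format)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
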