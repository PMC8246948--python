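"""End-to-end orchestration: generate -> extract -> kinematics -> epoch -> stats.

Two entry paths build the same per-trial :class:`~.alignment.AnalyzedTrial`
objects and then share all downstream stages:

* :func:`analyze_session_files` -- reads WAV/CSV trials from a manifest and
  extracts the acoustic tracks from audio (the full pipeline);
* :func:`analyze_simulated` -- consumes in-memory simulated trials using
  their ground-truth contours directly, which keeps large statistical
  validation loops cheap while the audio extraction stage is exercised by
  its own end-to-end suite.

Passive trials carry no movement, so their beat-locked trajectories are
defined through the surrogate pairing (passive speech aligned to borrowed
same-participant movement beats); those surrogate epochs serve as the
passive/baseline level of the trajectory models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import acoustics, alignment, kinematics, io_session as io, stats, synthetic

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one full run."""

    out_dir: str = "run"
    n_participants: int = 8
    trials_per_condition: int = 1
    master_seed: int = 1
    duration_mean_s: float = 26.0
    duration_sd_s: float = 7.0
    cutoff_hz: float = kinematics.DEFAULT_CUTOFF_HZ
    voicing_threshold: float = acoustics.VOICING_THRESHOLD
    min_gap_ms: float = 0.0
    epoch_window_ms: tuple = alignment.EPOCH_WINDOW_MS
    impulse_window_ms: tuple = alignment.IMPULSE_WINDOW_MS
    smooth_k: int = 10
    smooth_max_rows: int = 1_500_000

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SessionProducts:
    summaries: pd.DataFrame            # one row per trial
    epochs: pd.DataFrame               # long format incl. surrogate level
    trajectory_means: pd.DataFrame
    impulse_obs: pd.DataFrame
    impulse_trial_means: pd.DataFrame
    pairing: alignment.SurrogatePairing
    n_epochs: dict = field(default_factory=dict)


def _participant_scalers(trials: list[alignment.AnalyzedTrial]):
    """Per-participant pooled mean/SD for envelope and F0 (voiced frames)."""
    env_stats, f0_stats = {}, {}
    by_part: dict[str, list[alignment.AnalyzedTrial]] = {}
    for tr in trials:
        by_part.setdefault(tr.participant_id, []).append(tr)
    for pid, trs in by_part.items():
        env_stats[pid] = acoustics.participant_env_stats(
            [t.env for t in trs], [t.f0 for t in trs])
        pooled = np.concatenate([t.f0.f0[t.f0.voiced] for t in trs]) \
            if any(t.f0.voiced.any() for t in trs) else np.empty(0)
        f0_stats[pid] = ((float(pooled.mean()), float(pooled.std()))
                         if pooled.size else (np.nan, np.nan))
    return env_stats, f0_stats


def build_analyzed_trials(raw: list, config: RunConfig) -> list[alignment.AnalyzedTrial]:
    """Turn (entry-like, env, f0, motion) tuples into AnalyzedTrial objects.

    ``raw`` items: (participant_id, sex, trial_id, condition, env_track,
    f0_track, motion_or_None).  Beats are detected from the motion trace;
    envelope tracks are left on their native scale here (z-scaling is
    applied by :func:`process_session` with pooled participant stats).
    """
    out = []
    for pid, sex, tid, cond, env, f0, motion in raw:
        beats: list = []
        if motion is not None:
            kin = kinematics.smooth_and_differentiate(motion, config.cutoff_hz)
            beats = kinematics.detect_max_extensions(kin)
            beats = kinematics.annotate_deceleration(kin, beats)
        events = acoustics.segment_vocalizations(f0, env, config.min_gap_ms)
        out.append(alignment.AnalyzedTrial(
            participant_id=pid, sex=sex, trial_id=tid, condition=cond,
            env=env, f0=f0, beats=beats, events=events))
    return out


def analyze_simulated(trials: list[synthetic.SimTrial],
                      config: Optional[RunConfig] = None
                      ) -> list[alignment.AnalyzedTrial]:
    config = config or RunConfig()
    raw = [(t.participant_id, t.sex, t.trial_id, t.condition,
            t.truth.env_track(), t.truth.f0_track(), t.motion) for t in trials]
    return build_analyzed_trials(raw, config)


def analyze_session_files(manifest: io.SessionManifest,
                          config: Optional[RunConfig] = None
                          ) -> list[alignment.AnalyzedTrial]:
    config = config or RunConfig()
    raw = []
    for entry in manifest:
        rec = io.load_trial(entry)
        env = acoustics.compute_envelope(rec.audio)
        f0 = acoustics.track_f0(rec.audio, entry.sex,
                                voicing_threshold=config.voicing_threshold)
        # the envelope grid can be one sample longer; trim to the common grid
        n = min(len(env.env), len(f0.f0))
        env = acoustics.EnvelopeTrack(t=env.t[:n], env=env.env[:n], fs=env.fs)
        f0 = acoustics.F0Track(t=f0.t[:n], f0=f0.f0[:n], fs=f0.fs)
        raw.append((entry.participant_id, entry.sex, entry.trial_id,
                    entry.condition, env, f0, rec.motion))
    return build_analyzed_trials(raw, config)


def process_session(trials: list[alignment.AnalyzedTrial],
                    config: Optional[RunConfig] = None,
                    pairing_seed: int = 0) -> SessionProducts:
    """Shared downstream stages: z-scaling, epochs, surrogate, features."""
    config = config or RunConfig()
    env_stats, f0_stats = _participant_scalers(trials)

    scaled: list[alignment.AnalyzedTrial] = []
    summaries_rows = []
    for tr in trials:
        mu, sd = env_stats[tr.participant_id]
        env_z = tr.env.scaled(mu, sd)
        summ = acoustics.trial_acoustic_summary(tr.events, tr.f0, tr.env, (mu, sd))
        summaries_rows.append({
            "participant_id": tr.participant_id, "sex": tr.sex,
            "trial_id": tr.trial_id, "condition": tr.condition,
            "mean_f0": summ.mean_f0, "mean_env_z": summ.mean_env_z,
            "voc_duration_hz": summ.voc_duration_hz,
            "voc_interval_hz": summ.voc_interval_hz, "n_events": summ.n_events,
        })
        scaled.append(alignment.AnalyzedTrial(
            participant_id=tr.participant_id, sex=tr.sex, trial_id=tr.trial_id,
            condition=tr.condition, env=env_z, f0=tr.f0, beats=tr.beats,
            events=tr.events))
    summaries = pd.DataFrame(summaries_rows)

    real_epochs = []
    for tr in scaled:
        if tr.condition in io.MOVEMENT_CONDITIONS and tr.beats:
            real_epochs.extend(alignment.trial_epochs(tr, config.epoch_window_ms))
    pairing, surr_epochs = alignment.build_surrogate(
        scaled, pairing_seed, config.epoch_window_ms)

    epochs_df = alignment.epochs_to_frame(real_epochs + surr_epochs)
    sex_map = {tr.participant_id: tr.sex for tr in trials}
    epochs_df["sex"] = epochs_df["participant_id"].map(sex_map)
    mu_f0 = {p: s[0] for p, s in f0_stats.items()}
    sd_f0 = {p: s[1] for p, s in f0_stats.items()}
    epochs_df["f0_z"] = ((epochs_df["f0"] - epochs_df["participant_id"].map(mu_f0))
                         / epochs_df["participant_id"].map(sd_f0))

    traj = (alignment.average_trajectories(epochs_df, ("condition",), ("env", "f0"))
            if len(epochs_df) else pd.DataFrame())

    obs_frames = []
    for tr in scaled:
        if tr.condition not in io.MOVEMENT_CONDITIONS or not tr.beats:
            continue
        obs = alignment.impulse_window_features(
            tr.beats, tr.events, tr.env, tr.f0, config.impulse_window_ms)
        if obs.empty:
            continue
        obs.insert(0, "participant_id", tr.participant_id)
        obs.insert(1, "trial_id", tr.trial_id)
        obs.insert(2, "condition", tr.condition)
        obs_frames.append(obs)
    impulse_obs = (pd.concat(obs_frames, ignore_index=True) if obs_frames
                   else pd.DataFrame(columns=["participant_id", "trial_id",
                                              "condition", "cycle_index",
                                              "vocalization_id", "max_decel",
                                              "max_env", "max_f0"]))
    # z-scale max F0 per participant (affine, so z(max) == max(z))
    impulse_obs["max_f0_z"] = ((impulse_obs["max_f0"]
                                - impulse_obs["participant_id"].map(mu_f0))
                               / impulse_obs["participant_id"].map(sd_f0))
    trial_means = alignment.aggregate_impulse_observations(impulse_obs)
    if not trial_means.empty:
        tz = impulse_obs.groupby(["participant_id", "trial_id", "condition"],
                                 observed=True)["max_f0_z"].mean().reset_index()
        trial_means = trial_means.merge(
            tz, on=["participant_id", "trial_id", "condition"], how="left")

    n_epochs = {"real": len(real_epochs), "surrogate": len(surr_epochs),
                "samples_per_epoch": len(alignment.epoch_grid_ms(config.epoch_window_ms))}
    return SessionProducts(summaries=summaries, epochs=epochs_df,
                           trajectory_means=traj, impulse_obs=impulse_obs,
                           impulse_trial_means=trial_means, pairing=pairing,
                           n_epochs=n_epochs)


def gam_frame(products: SessionProducts) -> pd.DataFrame:
    """Epochs table for the trajectory models.

    The surrogate level (passive speech on borrowed beats) is relabeled
    ``passive``: it is the passive condition's beat-locked trajectory and
    serves as the model's reference level.
    """
    df = products.epochs.copy()
    df["condition"] = df["condition"].replace({"surrogate": "passive"})
    return df


def fit_all(products: SessionProducts, config: Optional[RunConfig] = None) -> dict:
    """Run the three statistical analyses on a processed session."""
    config = config or RunConfig()
    out: dict = {}
    out["condition_effects"] = stats.fit_condition_effects(products.summaries)
    gam = gam_frame(products)
    out["trajectory_smooths"] = {
        resp: stats.fit_trajectory_smooths(
            gam, response=resp, k=config.smooth_k,
            max_rows=config.smooth_max_rows)
        for resp in ("env", "f0_z")
    }
    if not products.impulse_trial_means.empty:
        # envelope peaks are already on the participant z-scale; use the
        # z-scaled F0 peaks as the F0 response as well
        tm = products.impulse_trial_means.copy()
        tm["max_f0"] = tm["max_f0_z"]
        out["deceleration_effects"] = stats.fit_deceleration_effects(tm)
    return out


def run_all(config: RunConfig) -> Path:
    """Full reproducible run: generate, analyze, fit, write tidy outputs."""
    out_dir = Path(config.out_dir)
    data_dir = out_dir / "session"
    manifest, _truths = synthetic.generate_session(
        data_dir, config.n_participants, config.trials_per_condition,
        config.master_seed, duration_mean_s=config.duration_mean_s,
        duration_sd_s=config.duration_sd_s)
    trials = analyze_session_files(manifest, config)
    products = process_session(trials, config, pairing_seed=config.master_seed)

    io.write_table(products.summaries, out_dir / "trial_summary.csv")
    io.write_table(products.epochs, out_dir / "epochs.csv")
    io.write_table(products.trajectory_means, out_dir / "trajectory_means.csv")
    io.write_table(products.impulse_obs, out_dir / "impulse_observations.csv")
    io.write_table(products.impulse_trial_means, out_dir / "impulse_trial_means.csv")

    fits = fit_all(products, config)
    rows = []
    for resp, effs in fits["condition_effects"].items():
        for e in effs:
            rows.append({"model": f"condition:{resp}", "term": e.term,
                         "b": e.b, "se": e.se, "stat": e.stat, "p": e.p})
    if "deceleration_effects" in fits:
        for resp, effs in fits["deceleration_effects"].items():
            for e in effs:
                rows.append({"model": f"deceleration:{resp}", "term": e.term,
                             "b": e.b, "se": e.se, "stat": e.stat, "p": e.p})
    for resp, sf in fits["trajectory_smooths"].items():
        for e in sf.parametric:
            rows.append({"model": f"trajectory:{resp}", "term": e.term,
                         "b": e.b, "se": e.se, "stat": e.stat, "p": e.p})
    io.write_table(pd.DataFrame(rows), out_dir / "model_estimates.csv")

    report = {
        "config": asdict(config),
        "n_trials": len(trials),
        "n_participants": products.summaries["participant_id"].nunique(),
        "conditions": sorted(products.summaries["condition"].unique()),
        "n_epochs": products.n_epochs,
        "surrogate_pairs": len(products.pairing.pairs),
        "trajectory_random_structure": {
            resp: sf.random_structure
            for resp, sf in fits["trajectory_smooths"].items()},
        "nonlinearity_p": {
            resp: sf.nonlinearity_p
            for resp, sf in fits["trajectory_smooths"].items()},
    }
    io.write_json(report, out_dir / "run_report.json")
    return out_dir
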