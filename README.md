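# gesturespeech

Analysis pipeline for **gesture–speech physics**: the biomechanical
hypothesis that rhythmic upper-limb movement perturbs the respiratory–vocal
system, so that fluent speech carries acoustic imprints of each movement
*beat*. The package takes per-trial audio (WAV, 44.1 kHz) and vertical limb
position (CSV, 240 Hz) for a within-subject design with three conditions —
`passive` (no movement), `wrist`, and `arm` — and computes the paradigm's
three headline statistics:

1. **Condition contrasts** — linear mixed models of per-trial mean F0 and
   amplitude envelope (z-scaled within participant), testing
   wrist-vs-passive and arm-vs-passive shifts with a participant random
   intercept (F0 models also adjust for speaker sex).
2. **Beat-locked trajectories** — acoustic epochs of −400…+400 ms around
   each *maximum extension* (the abrupt stop of the downstroke at the
   bottom of the movement), modeled with GAM-style smooth-by-condition
   regression; a surrogate pairing (passive speech re-aligned to borrowed
   same-participant movement beats) supplies the chance-level baseline.
3. **Deceleration scaling** — mixed regression of trial-averaged acoustic
   peaks on the maximum deceleration observed in the 200 ms before the
   extension (envelope: slope model; F0: condition × deceleration
   interaction, wrist reference).

Because higher-mass arm strokes carry larger physical impulse
(impulse = effector mass × Δvelocity), the paradigm predicts
arm > wrist > passive throughout.

A first-class synthetic-data generator (`gesturespeech.synthetic`) produces
full sessions — audio, motion, manifest — with *known* injected coupling
(a transient F0/envelope bump of height `mass_factor(condition) × β ×
max_decel` placed just before each beat), so every stage of the pipeline is
validated by parameter recovery against ground truth.

## Worked example

```python
from gesturespeech import pipeline as pl, stats as st, synthetic as syn

# 12 participants, 2 trials per condition, default coupling, fixed seed
trials = syn.simulate_session(12, 2, master_seed=303,
                              duration_mean_s=15.0, duration_sd_s=2.0)
products = pl.process_session(pl.analyze_simulated(trials), pairing_seed=303)

fits = st.fit_condition_effects(products.summaries)
for e in fits["mean_env_z"]:
    print(f"{e.term:20s} b={e.b:+.3f}  se={e.se:.3f}  p={e.p:.4f}")

sf = st.fit_trajectory_smooths(pl.gam_frame(products), response="env")
print("arm envelope peak at", sf.difference_peak_ms("arm"), "ms")
```

prints

```
intercept            b=-0.123  se=0.041  p=0.0123
arm_vs_passive       b=+0.277  se=0.071  p=0.0024
wrist_vs_passive     b=+0.068  se=0.057  p=0.2548
arm envelope peak at -87.5 ms
```

The arm condition raises the per-trial mean envelope by ~0.28 z-units over
passive (the injected arm coupling is twice the wrist's, which lands near
zero at this small sample), and the arm-vs-passive difference trajectory
peaks ~88 ms *before* maximum extension — inside the 0–200-ms
deceleration window where the physical-impulse account predicts acoustic
peaks.

A command-line interface mirrors the library
(`gesturespeech generate | extract | kinematics | epoch | stats | all`);
every stage reads and writes plain CSV, e.g.

```bash
gesturespeech all --out run --seed 1 --n-participants 8
```

writes the session, per-trial tracks, epochs, model estimates, and a
`run_report.json` with seeds and counts.

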