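# Methods

This note documents the models, algorithms, and numerical choices behind
the package, and what its synthetic validation does and does not show.

## The measurement model

One trial is ~10–40 s of fluent speech recorded at 44.1 kHz together with
(for movement conditions) the vertical position `z(t)` of the index finger
at 240 Hz, while the participant swings the wrist or the whole forearm at
a target tempo of 80 BPM (1.33 Hz; one cycle = 1000/1.33 ≈ 752 ms), with
instructions to end each downstroke in an abrupt stop — a *beat* — at the
lowest point (*maximum extension*). The physical-impulse hypothesis is
that the braking of the limb (its deceleration, scaled by effector mass)
transfers force through the trunk to the respiratory system and transiently
raises vocal intensity (amplitude envelope) and, more weakly, F0.

## Acoustic tracks

**Amplitude envelope.** Modulus of the analytic signal (Hilbert
transform), convolved with a Hann kernel of duration 1/5 s (a "5-Hz"
window; the kernel length is `fs/5` samples), then decimated to the
240-Hz motion grid by polyphase resampling with anti-alias filtering.
Interpreting the frequency-named window as a kernel of duration `1/f` is
the standard reading; the width is exposed as `smooth_hz`.

**F0.** Frame-wise normalized autocorrelation on the 240-Hz grid
(40-ms frames, audio decimated to ~11 kHz first), with sex-appropriate
search ranges (male 50–400 Hz, female 80–640 Hz). Design details that
matter:

* *unbiased lag normalization* — the windowed autocorrelation shrinks by
  `(1 − τ/N)`; we divide it out (clipped at 0.4) so long-period peaks
  compete fairly with short-lag structure;
* *candidate choice* — among near-equal local maxima (within 0.04) the
  shortest lag wins, which counters the octave-down bias the unbiased
  normalization would otherwise introduce;
* *voicing* — periodicity strength ≥ 0.45 (a configurable default; F0
  tracking always tolerates some noise), plus a consistency check: a frame
  whose unconstrained autocorrelation peak (searched beyond the zero-lag
  lobe, down to 40 Hz) is much stronger than the in-range peak and sits at
  a non-multiple lag has its true fundamental outside the range and is
  marked unvoiced. This makes a male-register tone under a female floor
  come out silent rather than mis-tracked;
* *octave-jump suppression* — within voiced runs, frames deviating >40%
  from the local median are re-picked at the nearest octave candidate;
* sub-sample lag refinement by parabolic interpolation (≈0.5-Hz accuracy
  at 200 Hz). Frames whose full analysis window does not fit inside the
  signal are unvoiced.

**Vocalization events** are maximal uninterrupted runs of voiced frames
(`min_gap_ms = 0` by default; micro-gap merging is available but off,
matching a strict "uninterrupted run" definition). Each event carries its
duration, envelope-peak time (the anchor for vocalization intervals), and
maximum F0. Trial rates convert milliseconds to hertz (1000/mean).

## Kinematics

Position is low-passed with a **first-order Butterworth at 30 Hz applied
forward–backward** (zero phase, so event times are not lag-shifted — the
filter order refers to the design; the effective magnitude response is
second order). Velocity and acceleration are central differences, each
re-filtered with the same filter; filtering position first and re-filtering
each derivative is a symmetric-noise-control choice where the convention
was ambiguous.

*Maximum extension* = local minima of filtered z (`scipy.signal.find_peaks`
with a minimum spacing of 0.4 s and a prominence of half the minimum
amplitude), refined to sub-sample precision with a local parabola. With z
up, the braking of the downstroke appears as positive acceleration;
`max_decel` is the absolutized maximum of that opposing acceleration in
the 200 ms before the extension. The *deceleration onset* is the time of
maximum downward speed (velocity minimum) in the preceding 400 ms — a
quarter period (~188 ms) before the extension on a pure sinusoid. Events
within 400 ms of the trace start are flagged invalid and excluded from
epoching. Note a small systematic effect: zero-phase smoothing of the
asymmetric beat valley biases the detected minimum a few milliseconds late
relative to the noiseless generator truth (observed ≤ 10 ms); beat
*matching* in the validation suite uses a 25-ms tolerance.

Movement tempo is the ridge (per-time power argmax) of a complex-Morlet
continuous wavelet transform (PyWavelets `cmor1.5-1.0`) over 0.6–3 Hz,
with 1-s edge trims; compliance is the fraction of ridge samples inside
the ±10% feedback region around 80 BPM (72–88 BPM).

## Alignment

Epochs slice the acoustic tracks onto a fixed −400…+400 ms grid (193
samples at 240 Hz, rel_t = 0 at the extension) by nearest-grid indexing —
no interpolation, F0 missingness preserved. Consecutive epochs may overlap
in absolute time (cycle ≈ 752 ms < 800 ms window); that is intentional.
Impulse windows are closed intervals `[t_ext − 200 ms, t_ext]`; each beat
contributes one observation per overlapping vocalization, with acoustic
maxima taken over the intersection.

**Surrogate baseline.** Passive trials have no movement, so their
beat-locked trajectories are *defined* by the surrogate pairing: each
passive trial's speech is epoched on the beats of a uniformly drawn
(seeded) same-participant movement trial, preserving temporal order;
donor beats beyond the speech duration are discarded. These surrogate
epochs serve double duty: they are the chance-level control *and* the
passive reference level of the trajectory models.

**Scaling.** The envelope is z-scaled per participant, pooled over all of
that participant's trials and conditions (so between-condition differences
survive) and restricted to voiced frames (pauses are near-zero and would
otherwise dominate the statistics). F0 enters the condition contrasts in
Hz and the trajectory/impulse models z-scaled the same way.

## Statistical models

* **Condition contrasts** and **deceleration effects** use statsmodels
  `MixedLM` with a participant random intercept (deceleration models
  attempt a random slope first). If the optimizer fails or does not
  converge — which happens systematically when the participant variance
  sits on the boundary, e.g. for within-participant z-scaled responses —
  the model falls back to OLS with participant-clustered standard errors,
  the matching inference for a zero variance component; a saturated
  design falls back to plain OLS. The structure actually used is recorded
  on the result. All p-values use a t reference with between-cluster
  degrees of freedom (G − 1), the conservative standard for
  cluster-robust inference; without it, 10-participant null simulations
  rejected at ~0.11 instead of 0.05.
* **Trajectory smooths** regress epoch samples on, per condition, a linear
  trend plus a cubic B-spline basis (default dimension k = 10)
  orthogonalized against {1, t} — so the spline block is *purely*
  nonlinear and its Wald test is exactly a nonlinearity test. Point
  estimates are least squares; all covariance is a participant-clustered
  sandwich, because the 193 samples within an epoch are strongly
  autocorrelated and any model-based SE is far too small (the naive Wald
  test rejected flat surrogate data at p ≈ 1e-12). The block test uses
  the Hotelling small-sample F correction
  `F = (G − q)/(q(G − 1)) · T² ~ F(q, G − q)`; with it, zero-coupling
  nonlinearity p-values are uniform-ish at both 12 and 37 participants.
  k = 10 keeps the block's q = 8 well below the cluster count; larger k
  (e.g. 20) re-inflates the test. An explicit participant random
  intercept is unnecessary here because the responses are z-scaled within
  participant; difference smooths (movement − passive) and their
  pointwise SEs come from the same sandwich.

## The synthetic generator

The generator is the package's ground-truth instrument; its defaults are
the study conditions, chosen once:

| parameter | default | why |
|---|---|---|
| movement tempo | wrist 1.44 Hz, arm 1.36 Hz (SD 0.05–0.08 within trial) | observed condition means around the 1.33-Hz target |
| stroke amplitude | wrist 10 cm, arm 25 cm (peak) | arm strokes are larger; drives arm > wrist deceleration |
| beat sharpness | 2.0 (power-law phase warp of the downstroke; 1 = sinusoid) | "abrupt stop": peak deceleration scales ≈ sharpness² |
| sensor noise | 0.05 cm SD | sub-millimeter tracker noise |
| trial duration | mean 26 s, SD 7, clipped 10–40 s | retelling times |
| voiced/pause runs | gamma, mean 160/200 ms | yields vocalization-duration rates ≈ 6 Hz |
| F0 baselines | female 210 Hz, male 137 Hz (intercept SD 10 Hz) | a 73-Hz sex gap, typical of read speech |
| coupling bump | Gaussian, FWHM 120 ms, centered −100 ms | mid-deceleration-phase acoustic peak |
| β_env | 1e-4 env-units per cm/s² | arm bumps ≈ 0.7 raw units ≈ visible but noisy |
| β_F0 | 1e-3 Hz per cm/s² | a deliberately smaller standardized effect than the envelope's |
| mass factor | passive 0, wrist 0.5, arm 1.0 | free 2:1 effector-mass ratio |

Bump gains are recorded per beat as
`mass_factor × β × max_decel` even when a bump falls wholly in a pause and
leaves no acoustic trace (F0 is only defined, and bumps only audible,
inside voiced intervals) — mirroring an analysis that can only see
vocalized windows. The true envelope contour is band-limited with the same
5-Hz Hann convention as the extraction stage: speech envelopes have no
step edges, and without this the end-to-end comparison confounds edge
blurring with extraction error. Audio is rendered as a 6-harmonic complex
(1/k roll-off) following the true F0, scaled by the true envelope, plus
low-level noise in pauses.

**What this emulates and what it does not.** The generator reproduces the
statistical structure the analysis assumes — quasi-periodic beats,
alternating voiced/pause speech, additive beat-locked prosodic bumps with
mass- and deceleration-dependent gains, participant heterogeneity — but
not articulation, formants, respiratory dynamics, F0 declination, or any
nonlinearity in how impulses are absorbed. Passing recovery tests
therefore shows the *pipeline* is correct and calibrated, not that real
gesture–speech coupling is additive or Gaussian-bumped.

**Validation loops.** The acoustic extraction stage is validated
end-to-end on rendered audio (tracked F0 RMSE < 3 Hz; envelope correlation
> 0.95). The statistical suites — parameter recovery with 37 participants
(the study's sample size; 2–4 trials per condition, ~18-s trials) and the
200-simulation null calibration (10 participants, 12-s trials) — run on
the generator's ground-truth contours fed through segmentation, alignment,
and model fitting. This keeps those loops at desk scale while every
processing stage is still exercised on its own oracle.

## Degenerate inputs and tie-breaks

Empty audio, stereo audio, unknown condition/sex labels, non-uniform
motion timestamps (gap > one sample period), passive trials with motion
paths, and all-equal envelopes (zero SD under z-scaling) raise explicit
errors. A flat motion trace yields no beats; an all-pause trial yields no
vocalization events and missing (not zero) trial rates. Impulse windows
are closed at both ends; a sample at exactly −200 or 0 ms is included.

## Known limitations

* The F0 tracker is an autocorrelation design, not the Schaefer–Vincent
  algorithm used historically in this paradigm; only voiced runs and F0
  values flow downstream, so tracker identity is encapsulated, but exact
  voicing boundaries can differ from other trackers on real data.
* Real-data coefficient values from the original paradigm depend on the
  archived recordings and are out of scope; the package's claims are
  recovery and calibration on known synthetic truth.
* The trajectory model's nonlinearity test needs cluster count ≫ spline
  df; with fewer than ~15 participants, treat its p-values as rough.
* Motion is one-dimensional (vertical); no gesture segmentation, phase
  grammars, or x/y analysis.
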