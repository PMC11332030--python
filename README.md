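# audiomotor

Analysis tools for auditory–motor synchronization experiments that compare
speech-associated and music-associated motor effectors (whispering vs
finger-tapping) synchronizing to syllable or piano-tone sequences at slow
(~2 Hz) and fast (~4.5 Hz) rates, plus the companion temporal
deviant-detection perception task.  It is written for researchers who need
a tested, scriptable version of this analysis chain — from raw audio or
envelope time series to per-condition synchronization scores, component
structure, and design-analysis numbers — together with a synthetic-study
generator with known ground truth for validating every step.

## What it computes

**Phase-locking value.** Synchronization between the acoustic stimulus
envelope and the motor-output envelope is quantified by the phase-locking
value over T samples,

    PLV = (1/T) | Σ_t exp(i(θ₁(t) − θ₂(t))) |

where θ₁, θ₂ are the instantaneous phases (Hilbert transform) of the two
band-limited envelopes.  Envelopes are extracted through a cochlear-style
gammatone filterbank (180–7246 Hz, 32 log-spaced channels), resampled to
100 Hz, and band-pass filtered around the stimulus rate: 3.5–5.5 Hz for
fast sequences, 1.56–2.44 Hz for slow ones.  The PLV is averaged over
sliding windows (5 s windows / 2 s overlap fast; 11 s / 4.5 s slow) and
normalized by subtracting a permutation baseline obtained by shuffling
contiguous windows of the acoustic envelope and re-running the filtering
and phase extraction.

**Stimulus schedules.** Accelerating sequences (e.g. 240 tokens stepping
1.92 → 2.08 Hz by 0.04 Hz every 48 tokens) for the synchronization task
and balanced isochronous deviant blocks for the perception task, with CSV
and JSON round-trips.

**Envelope features.** Sub-10 Hz amplitude-spectrum peak height and
full-width-half-maximum width, the per-trial covariates used in
downstream mixed models.

**Participant QC.** A consistency screen (trial 2 regressed on trial 1 per
condition; flags observations outside the 99% prediction band) and a
chance screen (exclusion when accuracy is at or below 0.5 in any
stimulus × rate cell).

**Component analysis and Bayes factors.** PCA of the eight condition
scores on the correlation matrix with Kaiser–Guttman retention
(eigenvalue ≥ 1) and varimax rotation; JZS Bayes factors for paired
t-tests (Cauchy prior, scale 1/√2) by numerical quadrature; Monte-Carlo
Bayes-factor design analysis (probability that a study of size n crosses
an evidence threshold at true effect d).

**Synthetic data.** An error-correcting phase oscillator renders motor
responses with tunable coupling, phase noise, lag, and effector-specific
burst shapes; a three-latent-component population model generates
per-participant condition couplings; a logistic psychometric model
generates deviant-detection responses.

## Worked example

```python
from audiomotor import (SLOW_BAND, OscillatorParams, make_accelerating_schedule,
                        permutation_baseline, simulate_motor_response)
from audiomotor.simulate import TAP_KERNEL, render_stimulus_envelope

schedule = make_accelerating_schedule(1.92, 2.08, 0.04, 24)   # ~60 s slow trial
stimulus = render_stimulus_envelope(schedule, "syllable")
params = OscillatorParams(coupling=0.8, phase_noise_sd=0.4, lag=0.03, rate_offset=0.02)
motor = simulate_motor_response(schedule, params, TAP_KERNEL, seed=7)
est = permutation_baseline(stimulus, motor, SLOW_BAND, n_permutations=50, seed=7)
print(f"raw {est.raw_plv:.3f}  baseline {est.baseline_plv:.3f}  "
      f"normalized {est.normalized_plv:.3f}")
```

prints

```
raw 0.945  baseline 0.512  normalized 0.433
```

A simulated tapper that corrects 80% of its phase error each cycle locks
tightly to the sequence (raw PLV 0.94); about 0.51 of that locking is
expected by chance for an envelope this rhythmic (the shuffle baseline),
leaving a normalized synchronization score of 0.43.  Running the same
trial at `coupling=0.2` gives a normalized PLV of 0.35 — the measure
tracks the underlying coupling.  The `examples/` directory holds short
narrative scripts for each capability: schedules, the PLV pipeline,
population PCA recovery, Bayes-factor design analysis, and perception QC.

A thin CLI mirrors the library for shell use:

```bash
audiomotor bfda --d 0.5 --n 62 --nsims 10000 --threshold 6 --seed 1
audiomotor analyze-sync --acoustic stim.wav --motor tap.wav --rate slow
audiomotor simulate-study --seed 1 --out study_out
```

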