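# Methods

This note documents the models, numerical choices, and known limitations
of `audiomotor`, in the spirit of the methods documentation of packages
like statsmodels or msprime.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Stimulus schedules

An accelerating sequence is defined by an inclusive rate grid
(`rate_start`, `rate_end`, `rate_step`) and a plateau length in tokens.
The first onset is at t = 0 and an event's nominal rate governs the
interval *following* it, so a plateau of k tokens at rate r contributes k
intervals of 1/r.  `OnsetSchedule.duration` includes the final token's
nominal duration (the slow 240-token sequence spans 120.096 s by this
definition; the sum of its 239 inter-onset intervals is 119.615 s, which
rounds to the same 120 s).  The grid must close on `rate_end` to within
1e-6 of a step, otherwise the parameters are rejected.

Perception blocks draw base rates with replacement from a five-point
multiplicative grid `rate_center · (1 + 0.02k)`, k ∈ {−2…2}.  For the
slow center (2.0 Hz) this gives exactly 1.92–2.08 Hz; for the fast center
(4.5 Hz) it gives 4.32–4.68 Hz, inside the nominal 4.3–4.7 Hz range.  The
multiplicative reading is pinned down by the slow grid.  Deviant shift
fractions are drawn from a continuous uniform distribution on the stated
range (syllables 0.28–0.34, tones 0.12–0.18 of the inter-onset interval);
exactly half of each block is deviant regardless of seed.

## Envelope extraction

Audio is converted to a 100 Hz amplitude envelope by: 32 gammatone
filters with log-spaced centre frequencies over 180–7246 Hz, per-channel
half-wave rectification, optional power-law compression (default exponent
0.3; disable via `compression=None`, which makes the extraction exactly
homogeneous of degree 1), channel summation, a 10 Hz zero-phase low-pass,
and polyphase resampling to 100 Hz.  This is a standard cochlear-style
front end, not a reimplementation of any particular auditory-model
toolbox; channel count, compression, and smoothing are arguments, and
numerical equivalence with other toolboxes' envelopes is not claimed.
The phase-locking analysis downstream only needs the envelope's slow
modulations, which are insensitive to these settings.

## Band-limited phase and windowed PLV

Rate bands are presets: fast = 3.5–5.5 Hz with 5 s windows and 2 s
overlap; slow = 1.56–2.44 Hz (the fast band scaled by 2.0/4.5) with 11 s
windows and 4.5 s overlap.  Band-passing uses a zero-phase (forward–
backward) Butterworth of order 4 per pass.  Because these bands are
narrow, the filter's impulse response rings for tens of seconds; the
input is therefore reflect-padded until the slowest pole has decayed
below 1e-9 (capped at the signal length), and inputs shorter than 3/lo
seconds are rejected.  Phase is the angle of the analytic signal.

Windows are aligned to trial start; a trailing partial window is
dropped; the trial's raw PLV is the unweighted mean over windows.

## Permutation baseline

The acoustic envelope is cut into contiguous segments of one window
length (trailing remainder dropped), the segment order is permuted
(identity permutations are redrawn whenever at least two segments exist,
since the identity would leak the raw PLV into the baseline), the
shuffled envelope is re-filtered and re-phased, and its windowed PLV
against the unshuffled motor phase is averaged over `n_permutations`
(default 100) draws.  The normalized PLV is raw − baseline.  Averaging
over permutations is a variance reduction of a single-shuffle estimator
of the same quantity.

**Baseline behavior for periodic stimuli.** For a strongly periodic
envelope, shuffling equal-length segments is close to phase-transparent:
each segment holds ~21–23 cycles, plateau rates differ by at most
0.16 Hz, and the windowed PLV is invariant to the constant phase offsets
that segment swaps introduce.  The baseline of a perfectly tracked slow
trial therefore measures ≈ 0.55, and even perfect synchrony yields a
normalized PLV of ≈ 0.45, not 1.  This is a property of the estimand,
not an implementation artifact: against a perfectly periodic stimulus,
chance alignment is genuinely high, which is exactly what the baseline
is designed to express.  The null calibration (independent
noise-modulated envelopes) centres the normalized PLV on 0 to within
±0.02.

## Synthetic data generator

Motor responses come from an error-correcting phase oscillator: the next
event is the previous event plus the intrinsic period, pulled toward the
nearest *upcoming* stimulus onset (plus a constant lag) by the coupling
fraction, with Gaussian per-event phase noise (radians, converted to
time via the current period) and an optional random-walk drift of the
intrinsic rate.  Referencing the nearest onset rather than an event
index lets the model re-anchor after missed events and follow
accelerating sequences without unwinding.  Defaults used by the study
pipeline: phase noise 0.4 rad/event, lag 30 ms, intrinsic rate detuned
+2% — values in the range of human tapping variability, chosen once for
realism.  Events are rendered as Gaussian bursts: taps narrow
(FWHM 30 ms), whisper syllables broader (FWHM 120 ms), with 10%
amplitude jitter; stimulus envelopes use 100 ms (syllable) and 50 ms
(tone) bursts.  Burst widths were chosen for clear separability of the
effector classes, not calibrated to any recording corpus.

Population structure: per-participant couplings for the eight conditions
are `base + L·z + ε` clipped to [0, 1], with three standard-normal
latents (fast-general, slow-whisper, slow-tap), loading 0.18 on their
conditions, base coupling 0.55, and independent noise (SD 0.04).
Clipping rather than a logistic squash keeps the latent-to-coupling map
affine where valid, which makes recovery tests exact.

Perception responses: P(report deviant | shift s) = guess + (1 − guess −
lapse) · logistic(slope·(s − threshold)) with guess 0.5, lapse 0.02,
slope 25 per unit shift fraction.  Standards are answered at the false
alarm rate implied by s = 0.  With the guess rate at 0.5, standards are
at chance by construction, so cell accuracy lives in [0.5, ~0.74];
thresholds are placed at or below the tested shift ranges (syllable:
0.22 fast / 0.30 slow; tone: 0.16 fast / 0.10 slow) so that deviant
accuracy stays well above chance, and their ordering produces the
rate × stimulus crossover (syllables easier fast, tones easier slow).

What the generator does *not* emulate: real syllable/tone acoustics
(envelopes are idealized burst trains), auditory feedback loops,
biomechanical limits on movement rates, serial-position or fatigue
effects, and between-trial learning.  Passing recovery tests therefore
show that the analysis chain measures what the simulator encodes, not
that it captures every property of human recordings.

## Component analysis

PCA operates on the correlation matrix of the standardized condition
scores; eigenvalues sum to the number of conditions.  Retention uses the
Kaiser–Guttman criterion applied inclusively (eigenvalue ≥ 1).  Varimax
rotation uses the SVD-based sweep algorithm with Kaiser normalization,
tolerance 1e-6, at most 1000 iterations; being orthogonal, it preserves
per-condition communalities exactly, and each component's
largest-magnitude loading is made positive for sign stability.  Because
varimax returns components in arbitrary order, recovery tests match
conditions to components by largest absolute loading rather than by
index.

## Bayes factors

The JZS Bayes factor for a paired/one-sample t-test places a
Cauchy(0, r) prior (default r = 1/√2) on the standardized effect size.
It is computed by marginalising over the inverse-gamma(1/2, r²/2)
mixing variable; substituting g = r²/(2v²) turns the mixing measure into
a half-normal weight, giving an integrand that adaptive quadrature
handles stably for any prior scale (including r → 0, where BF → 1).  The
null-likelihood factor is folded into the integrand in log space so the
ratio stays scaled for large |t|.  The implementation is cross-checked
in the tests against an independent formulation (Cauchy prior on the
effect × noncentral-t likelihood, dense trapezoid) to 1e-6 relative.

The design analysis draws n paired differences per replicate from
N(d, 1) — the standardized-effect convention — computes the one-sample
t, and converts it to BF₁₀.  Since BF₁₀ depends on t only through |t|
and is smooth, the 10,000 replicates are evaluated by log-interpolating
a 512-point quadrature grid over [0, max|t|], which is numerically
indistinguishable from per-replicate quadrature at a fraction of the
cost.  Default 10,000 replicates; the threshold BF₁₀ > 6 is the
moderate-evidence convention.

## QC screens

The consistency screen fits OLS per condition (trial 2 on trial 1) and
flags second-trial values outside the 99% **prediction** interval for a
new observation.  A mean-response confidence band is also available
(`interval="confidence"`) but would flag nearly everyone at large n; the
prediction-interval reading is the default and the documented
interpretation.  Conditions with zero trial-1 variance are skipped with
a warning.  The chance screen excludes participants at or below 0.5
accuracy in any stimulus × rate cell ("at or below" is deliberate: a
cell at exactly 0.5 excludes); participants missing a cell are reported
separately as incomplete rather than excluded.

## Simulation sizes in the test suite

The validation suite scales simulations for turnaround while keeping
full-length checks where the claim depends on length: the perfect
tracker's raw PLV is verified on the full 240-token slow trial; coupling
sweeps and the 200-participant PCA recovery use 60-token sequences
(~30 s slow trials) with 8 permutations and 2 trials per condition,
sizes at which the latent structure is comfortably recoverable; the null
calibration uses 100 seeded 45 s trials with 20 permutations.  The
design analysis always uses the full 10,000 replicates.

## Limitations

* Mixed-effects modelling, stepwise predictor selection, and post-hoc
  contrasts are out of scope; the pipeline exports tidy long-format
  tables for those tools.
* Envelope extraction is a generic cochlear-style front end; envelope
  values are not interchangeable with any specific auditory-model
  toolbox's output, though band-limited phases are robust to this.
* The permutation baseline saturates for strongly periodic stimuli (see
  above); normalized PLVs should be compared within, not across,
  stimulus rhythmicities.
* The loud-speaking exclusion of the original protocol is a manual
  annotation, not a computed screen.
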