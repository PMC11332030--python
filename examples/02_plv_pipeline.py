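"""One synchronization trial end to end: simulate a motor response to a
slow accelerating sequence, then score it with the windowed PLV and its
permutation baseline.

The normalized PLV (raw minus shuffle baseline) is the per-trial
synchronization measure; values near 0 mean chance-level alignment.
"""

from audiomotor import (
    SLOW_BAND,
    OscillatorParams,
    make_accelerating_schedule,
    permutation_baseline,
    simulate_motor_response,
)
from audiomotor.simulate import TAP_KERNEL, render_stimulus_envelope

schedule = make_accelerating_schedule(1.92, 2.08, 0.04, 24)  # ~60 s trial
stimulus_env = render_stimulus_envelope(schedule, "syllable")

for coupling in (0.2, 0.8):
    params = OscillatorParams(
        coupling=coupling, phase_noise_sd=0.4, lag=0.03, rate_offset=0.02
    )
    motor_env = simulate_motor_response(schedule, params, TAP_KERNEL, seed=7)
    est = permutation_baseline(
        stimulus_env, motor_env, SLOW_BAND, n_permutations=50, seed=7
    )
    print(
        f"coupling {coupling:.1f}: raw PLV {est.raw_plv:.3f}, "
        f"baseline {est.baseline_plv:.3f}, normalized {est.normalized_plv:.3f} "
        f"({est.n_windows} windows)"
    )
# A strongly coupled simulated tapper scores a clearly higher normalized
# PLV than a weakly coupled one; the baseline absorbs the locking any
# rhythmic envelope would show by chance.
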