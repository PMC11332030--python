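"""Build the stimulus timing structures used by both tasks.

An accelerating synchronization sequence steps its rate upward every fixed
number of tokens; a perception block is a balanced set of short isochronous
sequences, half of which end with an early ("deviant") final token.
"""

from audiomotor import make_accelerating_schedule, make_perception_block

# Slow synchronization sequence: 1.92 -> 2.08 Hz in 0.04 Hz steps,
# 48 tokens per plateau (240 tokens total).
slow = make_accelerating_schedule(1.92, 2.08, 0.04, 48)
print(f"slow sequence: {slow.n_events} events, {slow.duration:.3f} s total")
print(f"  IOI range: {slow.iois().min():.4f} - {slow.iois().max():.4f} s")

# Fast counterpart: 4.3 -> 4.7 Hz in 0.1 Hz steps.
fast = make_accelerating_schedule(4.3, 4.7, 0.1, 48)
print(f"fast sequence: {fast.n_events} events, {fast.duration:.3f} s total")

# A balanced deviant-detection block: 80 syllable sequences around 2 Hz,
# deviant shifts drawn from 28-34% of the inter-onset interval.
block = make_perception_block(
    "syllable", 80, rate_center=2.0, rate_grid_fraction=0.02, n_grid=5,
    shift_range=(0.28, 0.34), seed=1,
)
n_dev = sum(t.is_deviant for t in block.trials)
rates = sorted({round(t.base_rate, 2) for t in block.trials})
print(f"perception block: {len(block.trials)} trials, {n_dev} deviant ({100*n_dev/len(block.trials):.0f}%)")
print(f"  base-rate grid: {rates}")
# The 50% deviant proportion and the 1.92-2.08 Hz grid are design
# constants of the task; the deviant shift advances the final onset.
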