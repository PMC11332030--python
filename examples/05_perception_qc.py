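"""Deviant-detection responses and the participant QC screens.

Simulates a small cohort on the perception task from a logistic
psychometric model, tabulates accuracy per stimulus x rate cell, and
applies the two exclusion rules: the chance screen (accuracy at or below
0.5 in any cell) and the consistency screen (second-trial score outside
the 99% regression prediction band given the first trial).
"""

import numpy as np
import pandas as pd

from audiomotor import chance_screen, consistency_screen
from audiomotor.config import RunConfig
from audiomotor.pipeline import run_perception_analysis

cfg = RunConfig(seed=4, n_participants=8, n_perception_trials=80)
res = run_perception_analysis(cfg, "scratch/perception_demo")

acc = res["accuracy"].pivot_table(
    index="participant", columns=["stimulus", "rate"], values="accuracy"
)
print("accuracy per stimulus x rate cell:")
print(acc.round(2).to_string())
print()
report = res["report"]
print(f"chance screen (<= {report.chance_level}): excluded {sorted(report.excluded) or 'nobody'}")

# Consistency screen on synthetic trial-pair scores with one planted outlier.
rng = np.random.default_rng(0)
t1 = rng.uniform(0.1, 0.9, 20)
t2 = t1 + rng.normal(0, 0.02, 20)
t2[5] += 0.5  # this participant's second trial is wildly inconsistent
scores = pd.DataFrame(
    {"participant": [f"P{i:03d}" for i in range(20)], "condition": "tap_tone_slow",
     "trial1": t1, "trial2": t2}
)
cons = consistency_screen(scores, level=0.99)
print(f"consistency screen: flagged {sorted(cons.flagged) or 'nobody'}")
# Expected output: the syllable/tone accuracies cross over between fast
# and slow rates, and only the planted outlier P005 is flagged.
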