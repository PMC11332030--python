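"""Windowed phase-locking value with a permutation baseline.

The phase-locking value between two phase series θ₁, θ₂ over T samples is

    PLV = (1/T) |Σ_t exp(i(θ₁(t) − θ₂(t)))|

1 means a perfectly consistent phase relation, 0 none.  A trial's raw PLV
is the unweighted mean of PLVs over sliding windows (window length and
overlap come from the rate band).  Because raw PLVs are biased by trial
length and signal properties, a permutation baseline is subtracted: the
acoustic envelope is cut into contiguous windows, the windows are shuffled,
the band-filtering and phase extraction are re-run on the shuffled
envelope, and the windowed PLV against the *unshuffled* motor phase is
averaged over permutations.  The normalized PLV is raw − baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .envelopes import EnvelopeSignal, PhaseSeries, RateBand, bandpass_phase
from .errors import InvalidInputError

__all__ = [
    "PLVEstimate",
    "ConditionScore",
    "plv",
    "windowed_plv",
    "permutation_baseline",
    "score_condition",
]


@dataclass(frozen=True)
class PLVEstimate:
    raw_plv: float
    baseline_plv: float
    normalized_plv: float
    window_plvs: np.ndarray
    band: RateBand
    n_windows: int
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "window_plvs", np.asarray(self.window_plvs, dtype=float))


@dataclass(frozen=True)
class ConditionScore:
    participant_id: str
    effector: str
    stimulus: str
    rate: str
    plv: float
    n_trials: int


def _phase_diff(theta1, theta2) -> np.ndarray:
    p1 = theta1.phases if isinstance(theta1, PhaseSeries) else np.asarray(theta1, float)
    p2 = theta2.phases if isinstance(theta2, PhaseSeries) else np.asarray(theta2, float)
    if len(p1) != len(p2):
        raise InvalidInputError(f"phase series lengths differ: {len(p1)} vs {len(p2)}")
    if len(p1) == 0:
        raise InvalidInputError("phase series must contain at least one sample")
    if isinstance(theta1, PhaseSeries) and isinstance(theta2, PhaseSeries):
        if theta1.fs != theta2.fs:
            raise InvalidInputError("phase series sampling rates differ")
    return p1 - p2


def plv(theta1, theta2) -> float:
    """Phase-locking value of two equal-length phase series."""
    d = _phase_diff(theta1, theta2)
    return float(np.abs(np.mean(np.exp(1j * d))))


def window_starts(n_samples: int, fs: float, band: RateBand) -> np.ndarray:
    """Sample indices of window starts; trailing partial windows dropped."""
    win = int(round(band.window_s * fs))
    hop = int(round(band.hop_s * fs))
    if n_samples < win:
        raise InvalidInputError(
            f"series of {n_samples} samples shorter than one {band.window_s} s window"
        )
    return np.arange(0, n_samples - win + 1, hop)


def windowed_plv(
    theta1: PhaseSeries, theta2: PhaseSeries, band: RateBand
) -> tuple[float, np.ndarray]:
    """Mean PLV over sliding windows aligned to trial start."""
    d = _phase_diff(theta1, theta2)
    fs = theta1.fs if isinstance(theta1, PhaseSeries) else theta2.fs
    win = int(round(band.window_s * fs))
    starts = window_starts(len(d), fs, band)
    z = np.exp(1j * d)
    vals = np.array([np.abs(np.mean(z[s : s + win])) for s in starts])
    return float(vals.mean()), vals


def permutation_baseline(
    env_acoustic: EnvelopeSignal,
    env_motor: EnvelopeSignal,
    band: RateBand,
    n_permutations: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PLVEstimate:
    """Raw, baseline, and normalized windowed PLV for one trial.

    The acoustic envelope is segmented into contiguous windows of
    ``band.window_s`` (trailing remainder dropped), the segment order is
    permuted (identity permutations are redrawn), the shuffled envelope is
    re-filtered and re-phased, and its windowed PLV against the unshuffled
    motor phase forms the permutation distribution.
    """
    if env_acoustic.fs != env_motor.fs:
        raise InvalidInputError("envelopes must share a sampling rate")
    if n_permutations < 1:
        raise InvalidInputError("n_permutations must be at least 1")
    fs = env_acoustic.fs
    n = min(len(env_acoustic.samples), len(env_motor.samples))
    ac = EnvelopeSignal(env_acoustic.samples[:n], fs, env_acoustic.channel_label)
    mo = EnvelopeSignal(env_motor.samples[:n], fs, env_motor.channel_label)

    phase_mot = bandpass_phase(mo, band)
    phase_ac = bandpass_phase(ac, band)
    raw, window_plvs = windowed_plv(phase_ac, phase_mot, band)

    seg = int(round(band.window_s * fs))
    n_seg = n // seg
    if n_seg < 2:
        warnings.warn(
            "fewer than 2 permutation segments; baseline set to raw (normalized = 0)",
            stacklevel=2,
        )
        return PLVEstimate(raw, raw, 0.0, window_plvs, band, len(window_plvs), 0, seed)

    if rng is None:
        rng = np.random.default_rng(seed)
    trimmed = ac.samples[: n_seg * seg]
    segments = trimmed.reshape(n_seg, seg)
    mot_trim = PhaseSeries(phase_mot.phases[: n_seg * seg], fs, band)
    baseline_vals = np.empty(n_permutations)
    for i in range(n_permutations):
        order = rng.permutation(n_seg)
        while np.array_equal(order, np.arange(n_seg)):
            order = rng.permutation(n_seg)
        shuffled = EnvelopeSignal(segments[order].ravel(), fs, ac.channel_label)
        phase_shuf = bandpass_phase(shuffled, band)
        baseline_vals[i], _ = windowed_plv(phase_shuf, mot_trim, band)
    baseline = float(baseline_vals.mean())
    return PLVEstimate(
        raw, baseline, raw - baseline, window_plvs, band, len(window_plvs), n_permutations, seed
    )


def score_condition(
    trials: list[PLVEstimate],
    participant_id: str,
    effector: str,
    stimulus: str,
    rate: str,
) -> ConditionScore:
    """Average the normalized PLVs of a condition's trials."""
    if not trials:
        raise InvalidInputError("cannot score a condition with no trials")
    mean = float(np.mean([t.normalized_plv for t in trials]))
    return ConditionScore(participant_id, effector, stimulus, rate, mean, len(trials))
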