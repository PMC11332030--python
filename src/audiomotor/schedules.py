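"""Stimulus timing structures for synchronization and deviant-detection tasks.

Two kinds of schedule are produced here:

* **Accelerating sequences** used to probe spontaneous auditory–motor
  synchronization: the presentation rate steps upward by a fixed increment
  every fixed number of tokens (e.g. 4.3 → 4.7 Hz in 0.1 Hz steps every
  48 tokens, or 1.92 → 2.08 Hz in 0.04 Hz steps).
* **Isochronous deviant-detection sequences**: short runs of tokens at a
  constant rate in which, on deviant trials, the final onset is advanced by
  a fraction of the inter-onset interval (IOI).

Conventions: the first onset is at t = 0 and the rate attached to an event
governs the interval *following* it, so a plateau of 48 tokens at rate r
contributes 48 intervals of 1/r to the sequence span (the last token's
nominal duration is included in :attr:`OnsetSchedule.duration`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "OnsetSchedule",
    "PerceptionTrialSpec",
    "BlockSpec",
    "make_accelerating_schedule",
    "make_perception_trial",
    "make_perception_block",
]

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class OnsetSchedule:
    """Ordered event onsets with the nominal rate attached to each event.

    Parameters
    ----------
    onsets : ndarray
        Event times in seconds, strictly increasing, first onset at 0.
    rates : ndarray
        Nominal rate (Hz) of each event; an event's rate sets the interval
        that follows it.
    shifted_last : float
        Fraction of the final IOI by which the last onset was advanced
        (0 for non-deviant schedules).
    """

    onsets: np.ndarray
    rates: np.ndarray
    shifted_last: float = 0.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "rates", rates)
        if onsets.ndim != 1 or rates.ndim != 1 or len(onsets) != len(rates):
            raise InvalidParameterError("onsets and rates must be 1-D and equal length")
        if len(onsets) == 0:
            raise InvalidParameterError("schedule must contain at least one event")
        if abs(onsets[0]) > _GRID_TOL:
            raise InvalidParameterError("first onset must be at t = 0")
        if np.any(np.diff(onsets) <= 0):
            raise InvalidParameterError("onsets must be strictly increasing")
        if np.any(rates <= 0):
            raise InvalidParameterError("rates must be positive")
        if not 0.0 <= self.shifted_last < 1.0:
            raise InvalidParameterError("shifted_last must lie in [0, 1)")

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    @property
    def duration(self) -> float:
        """Span of the sequence including the final token's nominal duration."""
        return float(self.onsets[-1] + 1.0 / self.rates[-1])

    def iois(self) -> np.ndarray:
        """Inter-onset intervals (length ``n_events - 1``)."""
        return np.diff(self.onsets)

    def to_frame(self) -> pd.DataFrame:
        flags = np.zeros(self.n_events, dtype=bool)
        if self.shifted_last > 0:
            flags[-1] = True
        return pd.DataFrame(
            {
                "event_index": np.arange(self.n_events),
                "onset_s": self.onsets,
                "rate_hz": self.rates,
                "is_deviant_shifted": flags,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "OnsetSchedule":
        df = pd.read_csv(path_or_buf)
        shifted = 0.0
        if bool(df["is_deviant_shifted"].iloc[-1]) and len(df) >= 2:
            # recover the shift fraction from the final IOI deficit
            rate = float(df["rate_hz"].iloc[-2])
            ioi = float(df["onset_s"].iloc[-1] - df["onset_s"].iloc[-2])
            shifted = max(0.0, 1.0 - ioi * rate)
        return cls(df["onset_s"].to_numpy(), df["rate_hz"].to_numpy(), shifted)


@dataclass(frozen=True)
class PerceptionTrialSpec:
    """One deviant-detection trial: isochronous tokens, last one possibly early."""

    base_rate: float
    n_tokens: int
    is_deviant: bool
    shift_fraction: float = 0.0
    stimulus_class: str = "syllable"

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise InvalidParameterError("base_rate must be positive")
        if self.n_tokens < 2:
            raise InvalidParameterError("n_tokens must be at least 2")
        if not 0.0 <= self.shift_fraction < 1.0:
            raise InvalidParameterError("shift_fraction must lie in [0, 1)")
        if self.is_deviant != (self.shift_fraction > 0):
            raise InvalidParameterError("shift_fraction > 0 iff is_deviant")
        if self.stimulus_class not in ("syllable", "tone"):
            raise InvalidParameterError("stimulus_class must be 'syllable' or 'tone'")


@dataclass(frozen=True)
class BlockSpec:
    """A balanced block of perception trials, reproducible from its seed."""

    trials: tuple
    seed: int
    stimulus_class: str = "syllable"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_dev = sum(t.is_deviant for t in self.trials)
        if 2 * n_dev != len(self.trials):
            raise InvalidParameterError("exactly half of the trials must be deviant")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "stimulus_class": self.stimulus_class,
                "params": self.params,
                "trials": [
                    {
                        "base_rate": t.base_rate,
                        "n_tokens": t.n_tokens,
                        "is_deviant": t.is_deviant,
                        "shift_fraction": t.shift_fraction,
                        "stimulus_class": t.stimulus_class,
                    }
                    for t in self.trials
                ],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "BlockSpec":
        obj = json.loads(text)
        trials = tuple(PerceptionTrialSpec(**t) for t in obj["trials"])
        return cls(trials, obj["seed"], obj["stimulus_class"], obj["params"])


def make_accelerating_schedule(
    rate_start: float, rate_end: float, rate_step: float, tokens_per_step: int
) -> OnsetSchedule:
    """Build an accelerating onset schedule.

    The rate grid runs inclusively from ``rate_start`` to ``rate_end`` in
    increments of ``rate_step``; each rate holds for ``tokens_per_step``
    events.  Within a plateau every IOI equals 1/rate.

    Examples
    --------
    >>> s = make_accelerating_schedule(4.3, 4.7, 0.1, 48)
    >>> s.n_events
    240
    """
    if rate_start <= 0 or rate_end <= 0:
        raise InvalidParameterError("rates must be positive")
    if rate_start > rate_end:
        raise InvalidParameterError("rate_start must not exceed rate_end")
    if tokens_per_step < 1:
        raise InvalidParameterError("tokens_per_step must be at least 1")
    if rate_start == rate_end:
        grid = np.array([rate_start])
    else:
        if rate_step <= 0:
            raise InvalidParameterError("rate_step must be positive for an accelerating grid")
        n_steps_f = (rate_end - rate_start) / rate_step
        n_steps = int(round(n_steps_f))
        if abs(n_steps_f - n_steps) > 1e-6:
            raise InvalidParameterError(
                f"rate grid does not close on rate_end: ({rate_start}, {rate_end}, {rate_step})"
            )
        grid = rate_start + rate_step * np.arange(n_steps + 1)
    rates = np.repeat(grid, tokens_per_step)
    iois = 1.0 / rates[:-1]
    onsets = np.concatenate([[0.0], np.cumsum(iois)])
    return OnsetSchedule(onsets, rates)


def make_perception_trial(spec: PerceptionTrialSpec) -> OnsetSchedule:
    """Render a perception-trial spec as onsets: k/base_rate, last one
    advanced by ``shift_fraction``·IOI on deviant trials."""
    ioi = 1.0 / spec.base_rate
    onsets = np.arange(spec.n_tokens) * ioi
    if spec.is_deviant:
        onsets = onsets.copy()
        onsets[-1] -= spec.shift_fraction * ioi
    rates = np.full(spec.n_tokens, spec.base_rate)
    return OnsetSchedule(onsets, rates, shifted_last=spec.shift_fraction)


def make_perception_block(
    stimulus_class: str,
    n_trials: int,
    rate_center: float,
    rate_grid_fraction: float,
    n_grid: int,
    shift_range: tuple[float, float],
    seed: int,
    n_tokens: int = 10,
) -> BlockSpec:
    """Generate a balanced deviant-detection block.

    Exactly half of the trials are deviant; base rates are drawn uniformly
    (with replacement) from the multiplicative grid
    ``rate_center * (1 + rate_grid_fraction * k)`` with k centred on zero,
    and deviant shift fractions uniformly from ``shift_range``.
    """
    lo, hi = shift_range
    if n_trials % 2:
        raise InvalidParameterError("n_trials must be even for a balanced block")
    if n_trials < 2:
        raise InvalidParameterError("n_trials must be at least 2")
    if not (0.0 < lo <= hi < 1.0):
        raise InvalidParameterError("shift_range must satisfy 0 < lo <= hi < 1")
    if n_grid < 1 or n_grid % 2 == 0:
        raise InvalidParameterError("n_grid must be a positive odd count")

    rng = np.random.default_rng(seed)
    k = np.arange(n_grid) - (n_grid - 1) // 2
    grid = rate_center * (1.0 + rate_grid_fraction * k)

    deviant = np.zeros(n_trials, dtype=bool)
    deviant[: n_trials // 2] = True
    deviant = rng.permutation(deviant)
    base_rates = rng.choice(grid, size=n_trials)
    shifts = rng.uniform(lo, hi, size=n_trials)

    trials = tuple(
        PerceptionTrialSpec(
            base_rate=float(base_rates[i]),
            n_tokens=n_tokens,
            is_deviant=bool(deviant[i]),
            shift_fraction=float(shifts[i]) if deviant[i] else 0.0,
            stimulus_class=stimulus_class,
        )
        for i in range(n_trials)
    )
    params = {
        "n_trials": n_trials,
        "rate_center": rate_center,
        "rate_grid_fraction": rate_grid_fraction,
        "n_grid": n_grid,
        "shift_range": [lo, hi],
        "n_tokens": n_tokens,
    }
    return BlockSpec(trials, seed=seed, stimulus_class=stimulus_class, params=params)
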