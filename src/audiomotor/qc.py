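"""Participant-level quality control screens.

Two exclusion rules are implemented:

* **Consistency screen** — within each condition, an ordinary least squares
  regression predicts each participant's second-trial score from their
  first-trial score; a participant is flagged when the second-trial value
  falls outside the 99% interval at their first-trial value.  By default
  the *prediction* interval for a new observation is used (a mean-response
  confidence band would flag nearly everyone at large n); the
  mean-response band is available via ``interval="confidence"``.
* **Chance screen** — a participant is excluded when their accuracy is at
  or below chance (0.5 for the two-alternative deviant task) in at least
  one stimulus × rate cell; participants with missing cells are reported
  separately as incomplete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["ConsistencyReport", "ChanceReport", "consistency_screen", "chance_screen"]


@dataclass
class ConsistencyReport:
    interval_level: float
    interval_kind: str
    fits: dict  # condition -> {"slope", "intercept", "n"}
    flagged: dict = field(default_factory=dict)  # participant -> [conditions]

    @property
    def flagged_participants(self) -> set:
        return set(self.flagged)

    def to_json_dict(self) -> dict:
        return {
            "interval_level": self.interval_level,
            "interval_kind": self.interval_kind,
            "fits": self.fits,
            "flagged": {str(k): sorted(v) for k, v in self.flagged.items()},
        }


@dataclass
class ChanceReport:
    chance_level: float
    accuracy: pd.DataFrame  # participant, condition cells, accuracy
    excluded: set = field(default_factory=set)
    incomplete: set = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "chance_level": self.chance_level,
            "excluded": sorted(map(str, self.excluded)),
            "incomplete": sorted(map(str, self.incomplete)),
        }


def consistency_screen(
    scores: pd.DataFrame,
    level: float = 0.99,
    interval: str = "prediction",
) -> ConsistencyReport:
    """Flag participants whose trial-2 score is outside the regression band.

    Parameters
    ----------
    scores : DataFrame
        Long format with columns ``participant``, ``condition``, ``trial1``,
        ``trial2`` — one row per participant × condition.
    level : coverage of the interval (default 0.99).
    interval : ``"prediction"`` (new-observation band, default) or
        ``"confidence"`` (mean-response band).
    """
    if interval not in ("prediction", "confidence"):
        raise InvalidParameterError("interval must be 'prediction' or 'confidence'")
    if not 0 < level < 1:
        raise InvalidParameterError("level must be in (0, 1)")
    required = {"participant", "condition", "trial1", "trial2"}
    if not required.issubset(scores.columns):
        raise InvalidInputError(f"scores must have columns {sorted(required)}")

    fits: dict = {}
    flagged: dict = {}
    for cond, grp in scores.groupby("condition", sort=True):
        if len(grp) < 3:
            raise InvalidInputError(f"condition {cond!r} has fewer than 3 participants")
        x = grp["trial1"].to_numpy(dtype=float)
        y = grp["trial2"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"condition {cond!r}: trial-1 scores are constant; skipped",
                          stacklevel=2)
            continue
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        pred = fit.get_prediction(X).summary_frame(alpha=1.0 - level)
        if interval == "prediction":
            lo, hi = pred["obs_ci_lower"].to_numpy(), pred["obs_ci_upper"].to_numpy()
        else:
            lo, hi = pred["mean_ci_lower"].to_numpy(), pred["mean_ci_upper"].to_numpy()
        outside = (y < lo) | (y > hi)
        fits[str(cond)] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "n": int(len(grp)),
        }
        for pid in grp.loc[outside, "participant"]:
            flagged.setdefault(pid, []).append(str(cond))
    return ConsistencyReport(level, interval, fits, flagged)


def chance_screen(responses: pd.DataFrame, chance: float = 0.5) -> ChanceReport:
    """Exclude participants at or below chance accuracy in any cell.

    Parameters
    ----------
    responses : DataFrame
        Per-trial rows with columns ``participant``, ``stimulus``, ``rate``,
        ``correct`` (bool/0-1).
    """
    required = {"participant", "stimulus", "rate", "correct"}
    if not required.issubset(responses.columns):
        raise InvalidInputError(f"responses must have columns {sorted(required)}")
    acc = (
        responses.groupby(["participant", "stimulus", "rate"], sort=True)["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    cells = set(
        responses.groupby(["stimulus", "rate"], sort=True).groups
    )
    excluded, incomplete = set(), set()
    for pid, grp in acc.groupby("participant", sort=True):
        have = set(zip(grp["stimulus"], grp["rate"]))
        if have != cells:
            incomplete.add(pid)
            continue
        if (grp["accuracy"] <= chance).any():
            excluded.add(pid)
    return ChanceReport(chance, acc, excluded, incomplete)
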