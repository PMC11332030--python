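"""Simple audio renderers for listening checks.

A schedule can be rendered either as a click train (short raised-cosine
clicks at each onset) or as an amplitude-modulated tone whose modulation
follows Gaussian bursts at the onsets.  These are sanity-check stimuli,
not synthesized syllables or piano tones.
"""

from __future__ import annotations

import numpy as np

from .schedules import OnsetSchedule
from .simulate import render_burst_envelope

__all__ = ["schedule_to_click_train", "schedule_to_am_tone"]


def schedule_to_click_train(
    schedule: OnsetSchedule, fs: float = 44_100.0, click_ms: float = 5.0
) -> np.ndarray:
    """Render a schedule as a click train (float waveform in [-1, 1])."""
    n = int(np.ceil(schedule.duration * fs))
    out = np.zeros(n)
    click_n = max(int(round(click_ms / 1000.0 * fs)), 2)
    click = np.hanning(click_n)
    for te in schedule.onsets:
        i0 = int(round(te * fs))
        i1 = min(n, i0 + click_n)
        out[i0:i1] += click[: i1 - i0]
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def schedule_to_am_tone(
    schedule: OnsetSchedule,
    fs: float = 44_100.0,
    carrier_hz: float = 440.0,
    burst_fwhm: float = 0.08,
) -> np.ndarray:
    """Render a schedule as an amplitude-modulated carrier tone."""
    env = render_burst_envelope(
        schedule.onsets, schedule.duration, fs, burst_fwhm, channel_label="acoustic"
    )
    t = np.arange(len(env.samples)) / fs
    out = env.samples * np.sin(2.0 * np.pi * carrier_hz * t)
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out
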